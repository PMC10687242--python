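"""Hypothesis-level statistics for the microcosm analysis.

Three families:

* **PERMANOVA** — one-way permutational partitioning of distance-matrix
  variance (pseudo-F on squared distances), plus a mean-of-repetitions
  variant that reruns the test on independently rarefied tables and
  averages F, R-squared and p, so the reported test is not hostage to a
  single subsampling draw.
* **Consensus differential abundance** — a prevalence/total-abundance
  pre-filter, one built-in permutation test on log absolute abundances
  (external tools' per-ASV significance flags can be plugged in alongside),
  an all-methods consensus rule, and a fold-change reporting gate
  (treatment/control ratio below ``ratio_low`` or above ``ratio_high``).
* **Polynomial mixed trend models** — cubic (log10 density) or quadratic
  (ASV richness) day trends fully crossed with treatment and invader
  level, a random intercept per microcosm, and treatment-vs-control
  estimated-marginal-mean ratios with a Dunnett-style multiplicity
  adjustment within each day x invader-level family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import SimilarityMatrix, _metric_matrix
from .tables import AbsoluteTable, CountTable, SampleFrame, subsample_counts

__all__ = [
    "PermanovaResult",
    "DAConfig",
    "TrendModel",
    "permanova",
    "permanova_mean",
    "da_filter",
    "da_test_permutation",
    "da_consensus",
    "fit_trend_model",
    "emm_ratio_contrasts",
]


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    factor: str
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    repetitions_averaged: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-9):
            raise ValueError("r_squared outside [0, 1]")
        if self.p_value < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("p below the permutation floor")


def _as_distance(dist_or_sim) -> tuple[np.ndarray, list | None]:
    if isinstance(dist_or_sim, SimilarityMatrix):
        return 1.0 - dist_or_sim.values, dist_or_sim.sample_ids
    d = np.asarray(dist_or_sim, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    return d, None


def _permanova_ss(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray):
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    within = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / (2.0 * sizes)
    ss_within = within.sum()
    return ss_total - ss_within, ss_within


def permanova(
    dist_or_sim,
    groups,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
    factor: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA with free permutation of group labels.

    Partitions the sum of squared inter-point distances into among- and
    within-group components (pseudo-F), and estimates the p-value as
    ``(1 + #{permuted F >= observed F}) / (1 + n_permutations)``.
    """
    d, ids = _as_distance(dist_or_sim)
    groups = pd.Series(list(groups))
    n = d.shape[0]
    if len(groups) != n:
        raise ValueError("group labels do not match matrix size")
    levels, codes = np.unique(groups.to_numpy(), return_inverse=True)
    a = len(levels)
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = [str(levels[i]) for i in np.where(sizes < 2)[0]]
        raise ValueError(f"singleton groups: {small}")
    if rng is None:
        rng = np.random.default_rng()
    d2 = d.astype(float) ** 2

    def f_stat(c: np.ndarray) -> float:
        onehot = np.eye(a)[c]
        ss_a, ss_w = _permanova_ss(d2, onehot, sizes)
        return (ss_a / (a - 1)) / (ss_w / (n - a))

    onehot = np.eye(a)[codes]
    ss_a, ss_w = _permanova_ss(d2, onehot, sizes)
    ss_total = ss_a + ss_w
    f_obs = (ss_a / (a - 1)) / (ss_w / (n - a))
    exceed = 0
    for _ in range(n_permutations):
        # permuting codes keeps group sizes fixed while freely relabelling
        if f_stat(rng.permutation(codes)) >= f_obs - 1e-12:
            exceed += 1
    # ss_a can be slightly negative for semi-metric distances when the
    # grouping explains less than chance; report r^2 = 0 in that case
    return PermanovaResult(
        factor=factor,
        pseudo_F=float(f_obs),
        r_squared=float(max(ss_a, 0.0) / ss_total) if ss_total > 0 else 0.0,
        p_value=(1 + exceed) / (1 + n_permutations),
        n_permutations=n_permutations,
    )


def permanova_mean(
    counts: CountTable,
    groups,
    metric: str = "bray_curtis",
    depth: int = 26448,
    repetitions: int = 100,
    n_permutations: int = 999,
    seed: int = 3003,
    factor: str = "group",
) -> PermanovaResult:
    """Mean of ``repetitions`` PERMANOVAs over independent rarefactions.

    Each repetition rarefies the table to ``depth``, computes the metric's
    distance matrix and runs :func:`permanova`; the reported F, R-squared
    and p are means over repetitions.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    groups = pd.Series(list(groups), index=counts.sample_ids)
    fs, r2s, ps = [], [], []
    for _ in range(repetitions):
        sub, _excl = subsample_counts(counts, depth, rng)
        d = 1.0 - _metric_matrix(sub.counts.to_numpy(dtype=float), metric)
        res = permanova(d, groups.loc[sub.sample_ids], n_permutations, rng, factor)
        fs.append(res.pseudo_F)
        r2s.append(res.r_squared)
        ps.append(res.p_value)
    return PermanovaResult(
        factor=factor,
        pseudo_F=float(np.mean(fs)),
        r_squared=float(np.mean(r2s)),
        p_value=float(np.mean(ps)),
        n_permutations=n_permutations,
        repetitions_averaged=repetitions,
    )


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------


@dataclass
class DAConfig:
    """Filtering and reporting thresholds for differential abundance.

    ASVs are analysed only if their prevalence is at least
    ``min_prevalence`` and their summed absolute abundance at least
    ``min_total_absolute`` (both >= semantics); consensus hits are reported
    only when the treatment/control abundance ratio falls below
    ``ratio_low`` or above ``ratio_high``.
    """

    min_prevalence: float = 0.05
    min_total_absolute: float = 2500.0
    ratio_low: float = 0.2
    ratio_high: float = 5.0
    methods_required: int | None = None  # None = all supplied methods
    pseudocount: float = 1.0  # copies/mL guard for ratios and logs

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_prevalence < 1.0):
            raise ValueError("min_prevalence must be in [0, 1)")
        if not (0.0 < self.ratio_low < 1.0 < self.ratio_high):
            raise ValueError("need 0 < ratio_low < 1 < ratio_high")


def da_filter(
    abs_table: AbsoluteTable, config: DAConfig | None = None
) -> tuple[AbsoluteTable, pd.DataFrame]:
    """Drop rare/low-abundance ASVs before differential-abundance testing.

    Keeps ASVs with prevalence (fraction of samples with a positive value)
    >= ``min_prevalence`` AND summed absolute abundance >=
    ``min_total_absolute``.  Returns the filtered table and a removal
    report (asv_id, prevalence, total, reason).
    """
    config = config or DAConfig()
    vals = abs_table.values
    prevalence = (vals > 0).mean(axis=0)
    totals = vals.sum(axis=0)
    keep = (prevalence >= config.min_prevalence) & (totals >= config.min_total_absolute)
    removed = []
    for asv in vals.columns[~keep]:
        reasons = []
        if prevalence[asv] < config.min_prevalence:
            reasons.append("prevalence")
        if totals[asv] < config.min_total_absolute:
            reasons.append("total_abundance")
        removed.append(
            {
                "asv_id": asv,
                "prevalence": prevalence[asv],
                "total": totals[asv],
                "reason": "+".join(reasons),
            }
        )
    if keep.sum() == 0:
        raise ValueError("filter removed every ASV")
    filtered = AbsoluteTable(
        vals.loc[:, keep].copy(), abs_table.taxonomy[keep].copy()
    )
    return filtered, pd.DataFrame(removed, columns=["asv_id", "prevalence", "total", "reason"])


def da_test_permutation(
    abs_table: AbsoluteTable,
    group_a,
    group_b,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Permutation test of group mean differences in log absolute abundance.

    For each ASV the statistic is the difference of group means of
    ``log10(abundance + pseudocount)``; the two-sided p-value comes from
    free permutation of the sample labels (all ASVs share each permutation,
    which preserves between-ASV correlation), followed by Benjamini-
    Hochberg adjustment across ASVs.  Returns a frame with ``stat``, ``p``,
    ``p_adj`` and ``significant`` (p_adj <= alpha) per ASV.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("need at least 3 samples per group")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if rng is None:
        rng = np.random.default_rng()
    X = np.log10(abs_table.values.loc[group_a + group_b].to_numpy() + pseudocount)
    na = len(group_a)
    n = X.shape[0]

    def stat(idx_a: np.ndarray) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        mask[idx_a] = True
        return X[mask].mean(axis=0) - X[~mask].mean(axis=0)

    obs = stat(np.arange(na))
    exceed = np.zeros_like(obs)
    for _ in range(n_permutations):
        perm = rng.permutation(n)[:na]
        exceed += np.abs(stat(perm)) >= np.abs(obs) - 1e-12
    p = (1 + exceed) / (1 + n_permutations)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "asv_id": abs_table.asv_ids,
            "stat": obs,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj <= alpha,
        }
    ).set_index("asv_id")


def da_consensus(
    method_results: dict,
    abs_table: AbsoluteTable,
    group_a,
    group_b,
    config: DAConfig | None = None,
) -> pd.DataFrame:
    """Combine per-method significance flags into the conservative call.

    ``method_results`` maps method name -> boolean Series indexed by asv_id
    (externally produced flags — e.g. from corncob/DESeq2/ANCOM-BC runs —
    can be supplied directly).  An ASV is ``consensus`` when at least
    ``methods_required`` methods flag it (default: all supplied), and
    ``reported`` when additionally its treatment/control mean-abundance
    ratio is below ``ratio_low`` or above ``ratio_high``.
    """
    config = config or DAConfig()
    if not method_results:
        raise ValueError("no method results supplied")
    asv_ids = pd.Index(abs_table.asv_ids)
    flags = {}
    for name, res in method_results.items():
        s = res["significant"] if isinstance(res, pd.DataFrame) else pd.Series(res)
        if set(s.index) != set(asv_ids):
            raise ValueError(f"method {name!r} flags do not cover the table's ASVs")
        flags[name] = s.reindex(asv_ids).astype(bool)
    flag_frame = pd.DataFrame(flags)
    required = config.methods_required or len(method_results)
    n_flagged = flag_frame.sum(axis=1)
    mean_a = abs_table.values.loc[list(group_a)].mean(axis=0)
    mean_b = abs_table.values.loc[list(group_b)].mean(axis=0)
    ratio = (mean_a + config.pseudocount) / (mean_b + config.pseudocount)
    consensus = n_flagged >= required
    reported = consensus & ((ratio < config.ratio_low) | (ratio > config.ratio_high))
    out = pd.DataFrame(
        {
            "mean_abs_a": mean_a,
            "mean_abs_b": mean_b,
            "ratio": ratio,
            "n_methods_flagging": n_flagged,
            "consensus": consensus,
            "reported": reported,
        }
    )
    return pd.concat([flag_frame.add_prefix("sig_"), out], axis=1)


# ---------------------------------------------------------------------------
# Polynomial mixed trend models + marginal-mean ratio contrasts
# ---------------------------------------------------------------------------


@dataclass
class TrendModel:
    """Fitted polynomial mixed model for density or richness trends."""

    response: str  # 'log10_density' or 'richness'
    degree: int
    params: pd.Series
    cov: pd.DataFrame
    design_info: object
    estimator: str  # 'mixed' or 'ols_cluster'
    r_squared: float
    random_intercept_var: float
    day_range: tuple
    converged: bool = True
    data: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]


def _poly_terms(degree: int) -> str:
    terms = ["day"] + [f"I(day**{d})" for d in range(2, degree + 1)]
    return "(" + " + ".join(terms) + ")"


def fit_trend_model(
    values: pd.Series,
    samples: SampleFrame,
    response: str,
    degree: int | None = None,
) -> TrendModel:
    """Fit a polynomial day trend crossed with treatment and invader level.

    ``values`` holds the per-sample response indexed by sample_id: total
    cell density (cells/mL, log10-transformed internally) for
    ``response='log10_density'`` (cubic by default) or ASV richness for
    ``response='richness'`` (quadratic by default).  The model has fixed
    effects ``poly(day, degree) x treatment x invader_level`` and a random
    intercept per microcosm; singular mixed fits fall back to OLS with
    cluster-robust SEs, flagged in ``estimator``.
    """
    if response == "log10_density":
        degree = 3 if degree is None else degree
        y = np.log10(values.astype(float))
    elif response == "richness":
        degree = 2 if degree is None else degree
        y = values.astype(float)
    else:
        raise ValueError(f"unknown response {response!r}")
    meta = samples.frame.set_index("sample_id")
    missing = [s for s in values.index if s not in meta.index]
    if missing:
        raise ValueError(f"values without metadata: {missing}")
    df = meta.loc[values.index, ["microcosm_id", "day", "treatment", "invader_level"]].copy()
    df["y"] = y.to_numpy()
    df["day"] = df["day"].astype(float)
    cells = df.groupby(["treatment", "invader_level", "day"]).size()
    if (cells < 1).any():
        raise ValueError("design has empty treatment x invader x day cells")

    rhs = f"{_poly_terms(degree)}"
    if df["treatment"].nunique() > 1:
        rhs += " * C(treatment)"
    if df["invader_level"].nunique() > 1:
        rhs += " * C(invader_level)"
    formula = f"y ~ {rhs}"
    from .assembly import _mixed_or_ols

    params, cov, tag, res = _mixed_or_ols(formula, df, df["microcosm_id"])
    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = df["y"].to_numpy() - fitted
    sst = ((df["y"] - df["y"].mean()) ** 2).sum()
    r2 = float(1.0 - (resid**2).sum() / sst) if sst > 0 else 1.0
    re_var = 0.0
    if tag == "mixed":
        re_var = float(np.asarray(res.cov_re).ravel()[0])
    return TrendModel(
        response=response,
        degree=degree,
        params=params,
        cov=cov,
        design_info=res.model.data.design_info,
        estimator=tag,
        r_squared=r2,
        random_intercept_var=re_var,
        day_range=(float(df["day"].min()), float(df["day"].max())),
        data=df,
    )


def emm_ratio_contrasts(
    model: TrendModel,
    days=None,
    control: str = "none",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Treatment-vs-control estimated-marginal-mean ratios per day and level.

    For each day x invader level, computes the model's marginal mean for
    every treatment, forms the treatment/control ratio (back-transformed
    from log10 when the response is density) with a delta-method SE, and
    applies a Dunnett-style adjustment over the treatment-vs-control
    comparisons within that family (max-|z| under the joint normal of the
    contrasts; Holm fallback if the contrast covariance is degenerate).
    Requested days outside the fitted range raise (no extrapolation).
    """
    from patsy import build_design_matrices

    df = model.data
    days = sorted(df["day"].unique()) if days is None else list(days)
    lo, hi = model.day_range
    for d in days:
        if d < lo or d > hi:
            raise ValueError(f"day {d} outside fitted range [{lo}, {hi}]")
    treatments = [t for t in df["treatment"].unique() if t != control]
    if control not in set(df["treatment"]):
        raise ValueError(f"control level {control!r} absent from data")
    invaders = sorted(df["invader_level"].unique())
    beta = model.params.to_numpy()
    V = model.cov.to_numpy()

    def row(trt, inv, day) -> np.ndarray:
        at = pd.DataFrame(
            {"treatment": [trt], "invader_level": [inv], "day": [float(day)]}
        )
        return np.asarray(build_design_matrices([model.design_info], at)[0])[0]

    rows = []
    for day in days:
        for inv in invaders:
            contrasts, ses = [], []
            xc = row(control, inv, day)
            emm_c = float(xc @ beta)
            for trt in treatments:
                xt = row(trt, inv, day)
                L = xt - xc
                diff = float(L @ beta)
                se = float(np.sqrt(max(L @ V @ L, 0.0)))
                contrasts.append((trt, xt, L, diff, se))
                ses.append(se)
            # joint correlation of the family's contrasts for Dunnett max-|z|
            Ls = np.array([c[2] for c in contrasts])
            C = Ls @ V @ Ls.T
            for k, (trt, xt, L, diff, se) in enumerate(contrasts):
                emm_t = float(xt @ beta)
                if model.response == "log10_density":
                    ratio = 10.0 ** (emm_t - emm_c)
                    ratio_se = ratio * np.log(10.0) * se
                else:
                    if emm_c == 0:
                        raise ValueError("control marginal mean is zero")
                    ratio = emm_t / emm_c
                    g = xt / emm_c - emm_t * xc / emm_c**2
                    ratio_se = float(np.sqrt(max(g @ V @ g, 0.0)))
                z = diff / se if se > 0 else np.inf * np.sign(diff) if diff else 0.0
                p_raw = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
                p_adj = _dunnett_adjust(z, k, C) if len(contrasts) > 1 else p_raw
                rows.append(
                    {
                        "day": day,
                        "invader_level": inv,
                        "comparison": f"{trt}/{control}",
                        "emm_treatment": emm_t,
                        "emm_control": emm_c,
                        "ratio": ratio,
                        "ratio_se": ratio_se,
                        "z": z,
                        "p_raw": p_raw,
                        "p_adj": min(p_adj, 1.0),
                        "significant": p_adj <= alpha,
                    }
                )
    return pd.DataFrame(rows)


def _dunnett_adjust(z: float, which: int, C: np.ndarray) -> float:
    """Adjusted p for one contrast: P(max_j |Z_j| >= |z|) under joint normal."""
    se = np.sqrt(np.diag(C))
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        # degenerate covariance: Holm-style bound
        m = C.shape[0]
        return min(1.0, m * 2 * stats.norm.sf(abs(z)))
    R = C / np.outer(se, se)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    t = abs(z)
    m = R.shape[0]
    try:
        mvn = stats.multivariate_normal(mean=np.zeros(m), cov=R, allow_singular=True)
        inside = _mvn_rectangle(mvn, t, m)
    except (np.linalg.LinAlgError, ValueError):
        return min(1.0, m * 2 * stats.norm.sf(t))
    return max(1.0 - inside, 0.0)


def _mvn_rectangle(mvn, t: float, m: int) -> float:
    """P(-t <= Z_j <= t for all j) by inclusion-exclusion over orthants."""
    from itertools import product

    total = 0.0
    for signs in product((1, -1), repeat=m):
        upper = np.array([t if s == 1 else -t for s in signs])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            total += np.prod(signs) * mvn.cdf(upper)
    return float(total)
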