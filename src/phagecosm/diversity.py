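"""Alpha-diversity (Hill numbers), pairwise similarity, averaged matrices, PCoA.

Hill diversity of order q is the effective number of equally abundant taxa,
``D_q = (sum_i p_i^q)^(1/(1-q))``: q=0 is richness, q=1 the exponential of
Shannon entropy (limit), q=2 the inverse Simpson concentration.  Between-
sample similarity is quantified with the abundance-sensitive Bray-Curtis
index and the presence/absence Sorensen index, both on a 0..1 similarity
scale (1 = identical).  To remove depth artefacts, similarity matrices are
averaged over repeated rarefaction draws at a fixed read depth.  Ordination
is classical principal coordinates analysis on 1 - similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import CountTable, subsample_counts

__all__ = [
    "HillProfile",
    "SimilarityMatrix",
    "Ordination",
    "hill_diversity",
    "evenness",
    "hill_profile",
    "bray_curtis",
    "sorensen",
    "similarity_matrix",
    "averaged_similarity",
    "pcoa",
]

METRICS = ("bray_curtis", "sorensen")


def hill_diversity(counts, q: float) -> float:
    """Effective number of taxa of order ``q`` for one count/abundance vector.

    D_0 counts taxa present; D_1 = exp(Shannon entropy); D_2 = inverse
    Simpson; general q >= 0 via ``(sum p_i^q)**(1/(1-q))`` (continuous at
    q = 1).
    """
    x = np.asarray(counts, dtype=float)
    if q < 0:
        raise ValueError("q must be >= 0")
    if x.min() < 0:
        raise ValueError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValueError("zero-sum abundance vector")
    p = x[x > 0] / total
    if q == 0:
        return float(len(p))
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def evenness(counts, kind: str = "hill_ratio") -> float:
    """Evenness of a count vector.

    ``hill_ratio`` (default) is D_1/D_0, the effective fraction of common
    taxa; ``pielou`` is Shannon entropy over log richness.  Both equal 1
    exactly for a perfectly even community, and a single-taxon sample is
    defined as perfectly even.
    """
    if kind == "hill_ratio":
        return hill_diversity(counts, 1) / hill_diversity(counts, 0)
    if kind == "pielou":
        d0 = hill_diversity(counts, 0)
        if d0 == 1:
            return 1.0
        return float(np.log(hill_diversity(counts, 1)) / np.log(d0))
    raise ValueError(f"unknown evenness kind {kind!r}")


@dataclass
class HillProfile:
    """Per-sample Hill numbers (orders 0, 1, 2) and evenness."""

    frame: pd.DataFrame  # columns: sample_id, D0, D1, D2, evenness


def hill_profile(table: CountTable, orders=(0, 1, 2)) -> HillProfile:
    rows = []
    for sid in table.sample_ids:
        vec = table.counts.loc[sid].to_numpy()
        row = {"sample_id": sid}
        for q in orders:
            row[f"D{q:g}"] = hill_diversity(vec, q)
        row["evenness"] = evenness(vec)
        rows.append(row)
    return HillProfile(pd.DataFrame(rows))


def bray_curtis(x, y) -> float:
    """Bray-Curtis similarity ``1 - sum|x - y| / sum(x + y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    return float(1.0 - np.abs(x - y).sum() / (x + y).sum())


def sorensen(x, y) -> float:
    """Presence/absence Sorensen similarity ``2a / (2a + b + c)``.

    ``a`` counts shared taxa, ``b``/``c`` taxa unique to either sample;
    invariant to any positive rescaling of abundances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    px, py = x > 0, y > 0
    a = int((px & py).sum())
    b = int((px & ~py).sum())
    c = int((~px & py).sum())
    return float(2 * a / (2 * a + b + c))


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.min() < 0 or y.min() < 0:
        raise ValueError("negative abundances")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both vectors are all-zero")


@dataclass
class SimilarityMatrix:
    """Pairwise sample similarity under a named metric.

    ``averaged_over`` records how many rarefaction repetitions the matrix
    averages (1 = computed on the raw or a single rarefied table); ``depth``
    the rarefaction depth used (None = none).
    """

    sample_ids: list
    metric: str
    values: np.ndarray
    averaged_over: int = 1
    depth: int | None = None

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarities outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def lookup(self, a, b) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def subset(self, sample_ids) -> "SimilarityMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SimilarityMatrix(
            list(sample_ids),
            self.metric,
            self.values[np.ix_(idx, idx)].copy(),
            self.averaged_over,
            self.depth,
        )


def _metric_matrix(mat: np.ndarray, metric: str) -> np.ndarray:
    if metric == "bray_curtis":
        d = pdist(mat, metric="braycurtis")
    elif metric == "sorensen":
        d = pdist(mat > 0, metric="dice")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    sim = 1.0 - squareform(d)
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def similarity_matrix(table: CountTable, metric: str) -> SimilarityMatrix:
    """Pairwise similarity of all samples in a table (no rarefaction)."""
    mat = table.counts.to_numpy(dtype=float)
    if (mat.sum(axis=1) == 0).any():
        zero = [s for s, t in zip(table.sample_ids, mat.sum(axis=1)) if t == 0]
        raise ValueError(f"zero-read samples: {zero}")
    return SimilarityMatrix(table.sample_ids, metric, _metric_matrix(mat, metric))


def averaged_similarity(
    table: CountTable,
    metric: str | tuple = "bray_curtis",
    depth: int = 26448,
    repetitions: int = 100,
    seed: int = 3003,
) -> SimilarityMatrix | dict:
    """Mean of ``repetitions`` similarity matrices over rarefaction draws.

    Each repetition independently rarefies every sample to ``depth`` reads
    and computes the similarity matrix; the element-wise mean is returned
    with the averaging provenance recorded.  Passing a tuple of metrics
    computes all of them from the same rarefaction draws (statistically
    equivalent for the mean, and half the subsampling cost) and returns a
    dict keyed by metric.  Deterministic for a given seed.
    """
    metrics = (metric,) if isinstance(metric, str) else tuple(metric)
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    acc: dict[str, np.ndarray] = {}
    kept_ids: list | None = None
    for _ in range(repetitions):
        sub, _excluded = subsample_counts(table, depth, rng)
        if kept_ids is None:
            kept_ids = sub.sample_ids
        mat = sub.counts.to_numpy(dtype=float)
        for m in metrics:
            sim = _metric_matrix(mat, m)
            acc[m] = acc.get(m, 0.0) + sim
    out = {
        m: SimilarityMatrix(kept_ids, m, acc[m] / repetitions, repetitions, depth)
        for m in metrics
    }
    return out[metrics[0]] if isinstance(metric, str) else out


@dataclass
class Ordination:
    """PCoA result: centered sample coordinates plus eigen spectrum."""

    sample_ids: list
    coordinates: np.ndarray  # n x k, columns ordered by eigenvalue
    eigenvalues: np.ndarray  # all n eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def pcoa(sim: SimilarityMatrix, k: int | None = None) -> Ordination:
    """Classical (metric) principal coordinates analysis of ``1 - similarity``.

    Gower double-centering of ``-d^2/2`` followed by eigendecomposition.
    Axes with negative eigenvalues (non-Euclidean input) are reported but
    excluded both from the returned coordinates and from the explained-
    variance denominator; no Lingoes/Cailliez correction is applied.
    """
    n = len(sim.sample_ids)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d = 1.0 - sim.values
    d2 = d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1.0) * 1e-10
    positive = evals > tol
    n_pos = int(positive.sum())
    k_eff = n_pos if k is None else min(k, n_pos)
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    coords = coords - coords.mean(axis=0)  # numerically exact centering
    pos_sum = evals[positive].sum() if n_pos else 1.0
    return Ordination(
        sample_ids=list(sim.sample_ids),
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=evals[:k_eff] / pos_sum,
        negative_eigenvalues=evals[evals < -tol],
    )
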