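"""Tests for PERMANOVA, differential abundance and trend models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from conftest import random_count_table
from phagecosm.inference import (
    DAConfig,
    da_consensus,
    da_filter,
    da_test_permutation,
    emm_ratio_contrasts,
    fit_trend_model,
    permanova,
    permanova_mean,
)
from phagecosm.tables import AbsoluteTable, SampleFrame


def clusters(rng, sep=3.0, n=5, spread=0.1):
    pts = np.vstack([rng.normal(0, spread, (n, 2)), rng.normal(sep, spread, (n, 2))])
    return squareform(pdist(pts)), ["a"] * n + ["b"] * n


class TestPermanova:
    def test_separated_clusters_significant_and_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        d, labels = clusters(rng)
        res = permanova(d, labels, 999, rng)
        assert res.p_value <= 0.02
        assert res.r_squared > 0.99
        sk = sk_permanova(DistanceMatrix(d, [str(i) for i in range(10)]), labels, permutations=99)
        assert res.pseudo_F == pytest.approx(sk["test statistic"], rel=1e-10)

    def test_small_n_matches_exhaustive_enumeration(self, rng):
        # n = 4, 2 per group: compare sampled p with the full label shuffle law
        d = squareform(pdist(rng.normal(size=(4, 2))))
        labels = np.array([0, 0, 1, 1])
        res = permanova(d, labels, 9999, rng)

        def f_of(codes):
            return permanova(d, codes, 1, np.random.default_rng(0)).pseudo_F

        f_obs = f_of(labels)
        perms = [np.array(p) for p in itertools.permutations(labels)]
        exact = np.mean([f_of(p) >= f_obs - 1e-12 for p in perms])
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert res.p_value == pytest.approx(exact, abs=max(3 * se, 2e-3))

    def test_singleton_group_rejected(self, rng):
        d = squareform(pdist(rng.normal(size=(5, 2))))
        with pytest.raises(ValueError, match="singleton"):
            permanova(d, ["a", "a", "a", "a", "b"], 99, rng)

    def test_r_squared_and_floor_invariants(self, rng):
        d = squareform(pdist(rng.normal(size=(12, 2))))
        labels = ["a", "b", "c"] * 4
        res = permanova(d, labels, 99, rng)
        assert 0 <= res.r_squared <= 1
        assert res.p_value >= 1 / 100


class TestPermanovaMean:
    def test_single_repetition_reduces_to_plain_permanova(self, rng):
        table = random_count_table(rng, 8, 10, depth=500)
        groups = ["a"] * 4 + ["b"] * 4
        res1 = permanova_mean(table, groups, depth=200, repetitions=1, n_permutations=99, seed=5)
        assert res1.repetitions_averaged == 1
        res2 = permanova_mean(table, groups, depth=200, repetitions=1, n_permutations=99, seed=5)
        assert res1.pseudo_F == res2.pseudo_F and res1.p_value == res2.p_value

    def test_true_effect_gives_smaller_mean_p_than_shuffled_labels(self, rng):
        # two compositionally distinct groups
        probs_a = np.array([0.5, 0.3, 0.1, 0.05, 0.05])
        probs_b = np.array([0.05, 0.05, 0.1, 0.3, 0.5])
        mat = np.vstack(
            [rng.multinomial(500, probs_a, 4), rng.multinomial(500, probs_b, 4)]
        )
        from phagecosm.tables import CountTable

        table = CountTable(
            pd.DataFrame(mat, index=[f"s{i}" for i in range(8)], columns=list("abcde"))
        )
        groups = ["a"] * 4 + ["b"] * 4
        p_true = permanova_mean(table, groups, depth=300, repetitions=10, n_permutations=99, seed=1).p_value
        shuffled = ["a", "b"] * 4
        p_null = permanova_mean(table, shuffled, depth=300, repetitions=10, n_permutations=99, seed=1).p_value
        assert p_true < p_null


def abs_table_from(matrix, sample_ids, asv_ids):
    return AbsoluteTable(pd.DataFrame(matrix, index=sample_ids, columns=asv_ids))


class TestDAFilter:
    def test_low_prevalence_asv_removed(self):
        vals = np.full((40, 2), 100.0)
        vals[:, 1] = 0.0
        vals[0, 1] = 1e5  # 1 of 40 samples = 2.5% prevalence
        t = abs_table_from(vals, [f"s{i}" for i in range(40)], ["keep", "rare"])
        filt, report = da_filter(t, DAConfig())
        assert filt.asv_ids == ["keep"]
        assert report.loc[0, "asv_id"] == "rare" and "prevalence" in report.loc[0, "reason"]

    def test_total_abundance_boundary_is_inclusive(self):
        vals = np.array([[1250.0, 1249.0], [1250.0, 1250.0]])
        t = abs_table_from(vals, ["s1", "s2"], ["at_threshold", "below"])
        filt, report = da_filter(t, DAConfig(min_prevalence=0.05, min_total_absolute=2500))
        assert filt.asv_ids == ["at_threshold"]

    def test_zero_thresholds_are_identity(self, rng):
        vals = rng.uniform(0, 100, (6, 5))
        t = abs_table_from(vals, [f"s{i}" for i in range(6)], list("abcde"))
        filt, report = da_filter(t, DAConfig(min_prevalence=1e-12, min_total_absolute=0))
        assert filt.asv_ids == list("abcde") and report.empty

    def test_all_removed_is_an_error(self):
        t = abs_table_from(np.ones((4, 2)), list("wxyz"), ["a", "b"])
        with pytest.raises(ValueError):
            da_filter(t, DAConfig(min_total_absolute=1e9))


class TestDAPermutation:
    def test_null_groups_give_uniformish_p_and_no_bh_rejections(self, rng):
        rejections, pvals = [], []
        for _ in range(50):
            vals = rng.lognormal(8, 1, (10, 12))
            t = abs_table_from(vals, [f"s{i}" for i in range(10)], [f"a{j}" for j in range(12)])
            res = da_test_permutation(t, [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)], 199, rng)
            rejections.append(res["significant"].sum())
            pvals.extend(res["p"])
        assert np.mean(rejections) < 1.0
        # permutation p-values are superuniform-ish: mean near 0.5
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.06)

    def test_spiked_asv_has_smallest_p(self, rng):
        vals = rng.lognormal(8, 0.3, (10, 8))
        vals[:5, 3] *= 10  # 10-fold shift in group A
        t = abs_table_from(vals, [f"s{i}" for i in range(10)], [f"a{j}" for j in range(8)])
        res = da_test_permutation(t, [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)], 499, rng)
        assert res["p"].idxmin() == "a3"

    def test_matches_exhaustive_enumeration_at_n3_plus_3(self, rng):
        vals = rng.lognormal(8, 1, (6, 4))
        ids = [f"s{i}" for i in range(6)]
        t = abs_table_from(vals, ids, list("abcd"))
        res = da_test_permutation(t, ids[:3], ids[3:], 9999, rng)
        X = np.log10(vals + 1)
        obs = X[:3].mean(0) - X[3:].mean(0)
        exact = np.zeros(4)
        combos = list(itertools.combinations(range(6), 3))
        for combo in combos:
            mask = np.zeros(6, bool)
            mask[list(combo)] = True
            stat = X[mask].mean(0) - X[~mask].mean(0)
            exact += np.abs(stat) >= np.abs(obs) - 1e-12
        exact /= len(combos)
        np.testing.assert_allclose(res["p"], exact, atol=0.03)

    def test_degenerate_groups_rejected(self, rng):
        t = abs_table_from(np.ones((6, 2)), [f"s{i}" for i in range(6)], ["a", "b"])
        with pytest.raises(ValueError):
            da_test_permutation(t, ["s0", "s1"], ["s2", "s3", "s4"], 99, rng)


class TestDAConsensus:
    def make(self, ratio):
        vals = np.vstack([np.full((3, 1), 1000.0 * ratio), np.full((3, 1), 1000.0)])
        return abs_table_from(vals, [f"s{i}" for i in range(6)], ["asv"]), \
            [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)]

    def flags(self, *vals):
        return {f"m{i}": pd.Series({"asv": v}) for i, v in enumerate(vals)}

    def test_flagged_by_all_with_extreme_ratio_is_reported(self):
        t, ga, gb = self.make(0.1)
        out = da_consensus(self.flags(True, True, True), t, ga, gb)
        assert bool(out.loc["asv", "consensus"]) and bool(out.loc["asv", "reported"])

    def test_flagged_by_two_of_three_is_not_consensus(self):
        t, ga, gb = self.make(0.1)
        out = da_consensus(self.flags(True, True, False), t, ga, gb)
        assert not bool(out.loc["asv", "consensus"]) and not bool(out.loc["asv", "reported"])

    def test_consensus_with_moderate_ratio_is_not_reported(self):
        t, ga, gb = self.make(1.0)
        out = da_consensus(self.flags(True, True, True), t, ga, gb)
        assert bool(out.loc["asv", "consensus"]) and not bool(out.loc["asv", "reported"])

    def test_methods_required_override(self):
        t, ga, gb = self.make(10.0)
        out = da_consensus(
            self.flags(True, True, False), t, ga, gb, DAConfig(methods_required=2)
        )
        assert bool(out.loc["asv", "reported"])

    def test_mismatched_asv_sets_rejected(self):
        t, ga, gb = self.make(1.0)
        with pytest.raises(ValueError, match="m0"):
            da_consensus({"m0": pd.Series({"other": True})}, t, ga, gb)


def trend_design(days=(0, 1, 3, 7), treatments=("none", "antibiotic"), n_reps=3):
    rows = []
    for trt in treatments:
        for rep in range(1, n_reps + 1):
            for day in days:
                rows.append(
                    dict(
                        sample_id=f"{trt}{rep}d{day}",
                        microcosm_id=f"{trt}{rep}",
                        replicate=rep,
                        day=day,
                        treatment=trt,
                        invader_level="no",
                    )
                )
    return SampleFrame(pd.DataFrame(rows))


class TestTrendModel:
    def test_zero_noise_cubic_recovered_exactly(self):
        samples = trend_design(treatments=("none",))
        meta = samples.frame
        dens = 10 ** (6 + 0.3 * meta.day - 0.08 * meta.day**2 + 0.005 * meta.day**3)
        model = fit_trend_model(pd.Series(dens.to_numpy(), index=meta.sample_id), samples, "log10_density")
        beta = model.params
        assert beta["Intercept"] == pytest.approx(6.0, abs=1e-6)
        assert beta["day"] == pytest.approx(0.3, abs=1e-6)
        assert beta["I(day ** 2)"] == pytest.approx(-0.08, abs=1e-6)
        assert beta["I(day ** 3)"] == pytest.approx(0.005, abs=1e-6)
        assert model.r_squared > 1 - 1e-9

    def test_random_intercepts_recovered_within_2se(self):
        rng = np.random.default_rng(21)
        hits = 0
        n_fits = 30
        for _ in range(n_fits):
            samples = trend_design(treatments=("none",), n_reps=6)
            meta = samples.frame
            micro_fx = {m: rng.normal(0, 0.2) for m in meta.microcosm_id.unique()}
            y = (
                6 + 0.25 * meta.day - 0.04 * meta.day**2
                + meta.microcosm_id.map(micro_fx) + rng.normal(0, 0.05, len(meta))
            )
            model = fit_trend_model(
                pd.Series((10.0**y).to_numpy(), index=meta.sample_id),
                samples, "log10_density", degree=2,
            )
            se = np.sqrt(np.diag(model.cov.to_numpy()))
            beta = model.params.to_numpy()
            truth = np.array([6, 0.25, -0.04])
            hits += np.all(np.abs(beta - truth) <= 2 * se)
        assert hits >= int(0.85 * n_fits)

    def test_quadratic_richness_default_degree(self):
        samples = trend_design(treatments=("none",))
        meta = samples.frame
        rich = 60 - 2 * meta.day + 0.1 * meta.day**2
        model = fit_trend_model(pd.Series(rich.to_numpy(), index=meta.sample_id), samples, "richness")
        assert model.degree == 2
        assert model.params["day"] == pytest.approx(-2.0, abs=1e-6)


class TestEMMRatios:
    def test_identical_groups_ratio_one_p_near_one(self):
        # the two treatments receive literally the same replicate values, so
        # the contrast is zero against a well-defined residual SE
        rng = np.random.default_rng(17)
        samples = trend_design()
        meta = samples.frame
        noise = {
            (rep, day): rng.normal(0, 0.05)
            for rep in meta.replicate.unique()
            for day in meta.day.unique()
        }
        y = 6 + 0.1 * meta.day + np.array(
            [noise[(r, d)] for r, d in zip(meta.replicate, meta.day)]
        )
        model = fit_trend_model(
            pd.Series((10.0**y).to_numpy(), index=meta.sample_id),
            samples, "log10_density",
        )
        out = emm_ratio_contrasts(model)
        np.testing.assert_allclose(out["ratio"], 1.0, atol=1e-6)
        assert (out["p_adj"] > 0.9).all()

    def test_constant_twofold_offset_recovered(self):
        rng = np.random.default_rng(3)
        samples = trend_design(n_reps=5)
        meta = samples.frame
        base = 6 + 0.1 * meta.day
        y = base + np.where(meta.treatment == "antibiotic", np.log10(2.0), 0.0)
        y = y + rng.normal(0, 0.02, len(meta))
        model = fit_trend_model(
            pd.Series((10.0**y).to_numpy(), index=meta.sample_id), samples, "log10_density"
        )
        out = emm_ratio_contrasts(model)
        np.testing.assert_allclose(out["ratio"], 2.0, rtol=0.10)

    def test_ratios_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(9)
        samples = trend_design()
        meta = samples.frame
        y = 10 ** (6 + 0.1 * meta.day + rng.normal(0, 0.05, len(meta)))
        m1 = fit_trend_model(pd.Series(y.to_numpy(), index=meta.sample_id), samples, "log10_density")
        m2 = fit_trend_model(pd.Series(y.to_numpy() * 7.3, index=meta.sample_id), samples, "log10_density")
        r1 = emm_ratio_contrasts(m1)["ratio"].to_numpy()
        r2 = emm_ratio_contrasts(m2)["ratio"].to_numpy()
        np.testing.assert_allclose(r1, r2, rtol=1e-8)

    def test_geometric_mean_ratio_identity_on_balanced_noiseless_data(self):
        samples = trend_design()
        meta = samples.frame
        y = 10 ** (6 + 0.2 * meta.day + np.where(meta.treatment == "antibiotic", -0.3, 0.0))
        model = fit_trend_model(pd.Series(y.to_numpy(), index=meta.sample_id), samples, "log10_density")
        out = emm_ratio_contrasts(model, days=[7])
        # geometric-mean ratio of the raw data at day 7
        at7 = meta[meta.day == 7]
        ab = y[at7.index[at7.treatment == "antibiotic"]]
        no = y[at7.index[at7.treatment == "none"]]
        gm_ratio = np.exp(np.log(ab).mean() - np.log(no).mean())
        assert out["ratio"].iloc[0] == pytest.approx(gm_ratio, abs=1e-9)

    def test_extrapolation_rejected(self):
        samples = trend_design()
        meta = samples.frame
        dens = pd.Series(np.full(len(meta), 1e6), index=meta.sample_id)
        model = fit_trend_model(dens, samples, "log10_density")
        with pytest.raises(ValueError, match="outside"):
            emm_ratio_contrasts(model, days=[10])
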