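"""t-test vectorization, candidate gates, permutation null, power, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster

from helptag_dm.containers import MethylationMatrix
from helptag_dm.differential import (analytic_power, cluster_loci,
                                     direction_enrichment, loci_t_test,
                                     permutation_correction,
                                     power_simulation, select_candidates)


def matrix_from_arrays(a: np.ndarray, b: np.ndarray,
                       ga="Con", gb="UN") -> MethylationMatrix:
    n = a.shape[0]
    loci = pd.DataFrame({
        "locus_id": [f"L{i}" for i in range(n)], "chrom": "chr1",
        "start": np.arange(n) * 2000 + 1000, "end": np.arange(n) * 2000 + 1004,
    })
    cols_a = [f"{ga}{i}" for i in range(a.shape[1])]
    cols_b = [f"{gb}{i}" for i in range(b.shape[1])]
    scores = pd.DataFrame(
        np.clip(np.hstack([a, b]), 0, 100),
        index=pd.Index(loci["locus_id"], name="locus_id"),
        columns=cols_a + cols_b)
    groups = pd.Series({**{c: ga for c in cols_a}, **{c: gb for c in cols_b}})
    return MethylationMatrix(loci, scores, groups)


class TestLociTTest:
    def test_worked_pooled_t_example(self):
        mat = matrix_from_arrays(np.array([[10.0, 20, 30]]),
                                 np.array([[40.0, 50, 60]]))
        res = loci_t_test(mat, "Con", "UN").iloc[0]
        assert res["delta"] == pytest.approx(30.0)
        assert abs(res["t_stat"]) == pytest.approx(3.674235, abs=1e-6)
        assert res["p_value"] == pytest.approx(0.021312, abs=1e-6)

    def test_identical_groups_null(self):
        mat = matrix_from_arrays(np.array([[10.0, 20, 30]]),
                                 np.array([[10.0, 20, 30]]))
        res = loci_t_test(mat, "Con", "UN").iloc[0]
        assert res["delta"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_degenerate_zero_variance_untestable(self):
        mat = matrix_from_arrays(np.array([[5.0, 5, 5]]),
                                 np.array([[5.0, 5, 5]]))
        res = loci_t_test(mat, "Con", "UN").iloc[0]
        assert not res["testable"]

    def test_unknown_group_rejected(self, small_matrix):
        with pytest.raises(KeyError):
            loci_t_test(small_matrix, "Con", "Nope")

    def test_vectorized_agrees_with_scalar_oracle(self):
        rng = np.random.default_rng(42)
        a = rng.uniform(0, 100, size=(100, 5))
        b = rng.uniform(0, 100, size=(100, 6))
        mat = matrix_from_arrays(a, b)
        res = loci_t_test(mat, "Con", "UN")
        for i in range(100):
            t_ref, p_ref = stats.ttest_ind(b[i], a[i], equal_var=True)
            assert res["t_stat"].iloc[i] == pytest.approx(t_ref, rel=1e-10)
            assert res["p_value"].iloc[i] == pytest.approx(p_ref, rel=1e-10)


class TestSelectCandidates:
    @pytest.mark.parametrize("delta,p,kept", [
        (35.0, 0.001, True),
        (-35.0, 0.001, True),
        (29.9, 1e-6, False),   # delta gate is strict
        (60.0, 0.01, False),   # p gate
        (30.0, 0.001, False),  # boundary excluded (strict >)
        (35.0, 0.005, False),  # boundary excluded (strict <)
    ])
    def test_gates(self, delta, p, kept):
        res = pd.DataFrame({
            "locus_id": ["L0"], "chrom": ["chr1"], "start": [0], "end": [1],
            "delta": [delta], "p_value": [p], "testable": [True]})
        out = select_candidates(res)
        assert (len(out) == 1) is kept

    def test_sorted_by_p_then_abs_delta(self):
        res = pd.DataFrame({
            "locus_id": list("abcd"), "chrom": "chr1",
            "start": range(4), "end": range(1, 5),
            "delta": [40.0, 50.0, -45.0, 35.0],
            "p_value": [1e-3, 1e-4, 1e-4, 1e-2],
            "testable": True})
        out = select_candidates(res, max_p=0.05)
        assert list(out["locus_id"]) == ["b", "c", "a", "d"]


class TestDirectionEnrichment:
    @staticmethod
    def frame_from_table(c_hyper, c_hypo, n_hyper, n_hypo):
        n = c_hyper + c_hypo + n_hyper + n_hypo
        delta = np.concatenate([
            np.full(c_hyper, -40.0), np.full(c_hypo, 40.0),
            np.full(n_hyper, -5.0), np.full(n_hypo, 5.0)])
        cand = np.concatenate([
            np.ones(c_hyper + c_hypo, bool), np.zeros(n_hyper + n_hypo, bool)])
        return pd.DataFrame({
            "locus_id": [f"L{i}" for i in range(n)], "chrom": "chr1",
            "start": range(n), "end": range(1, n + 1), "delta": delta,
            "p_value": np.where(cand, 1e-4, 0.5), "testable": True,
            "candidate": cand})

    def test_hand_table_odds_ratio_and_exact_p(self):
        res = self.frame_from_table(30, 10, 470, 490)
        odds, p = direction_enrichment(res)
        assert odds == pytest.approx(3.12766, abs=1e-4)
        # independent oracle: sum hypergeometric point masses at least as
        # extreme as the observed table
        oracle = stats.fisher_exact([[30, 10], [470, 490]])[1]
        assert p == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(0.0018083, abs=1e-6)

    def test_balanced_table_null(self):
        res = self.frame_from_table(20, 20, 480, 480)
        odds, p = direction_enrichment(res)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_all_hyper_candidates_infinite_odds(self):
        res = self.frame_from_table(25, 0, 500, 500)
        odds, p = direction_enrichment(res)
        assert np.isinf(odds)
        assert 0 < p < 0.001

    def test_empty_stratum_warns(self):
        res = self.frame_from_table(0, 0, 500, 500)
        with pytest.warns(UserWarning, match="empty stratum"):
            _, p = direction_enrichment(res)
        assert p == 1.0


class TestPermutationCorrection:
    def test_extreme_candidate_survives(self):
        rng = np.random.default_rng(0)
        a = rng.normal(50, 10, size=(400, 5))
        b = rng.normal(50, 10, size=(400, 6))
        a[0], b[0] = 10.0, 90.0  # far beyond any permuted statistic
        a[0] += rng.normal(0, 0.5, 5)
        b[0] += rng.normal(0, 0.5, 6)
        mat = matrix_from_arrays(a, b)
        res = loci_t_test(mat, "Con", "UN")
        select_candidates(res)
        corr = permutation_correction(mat, "Con", "UN", res,
                                      n_perm=100, seed=1)
        assert bool(corr.corrected.loc["L0"])

    def test_null_pass_rate_near_2_5_percent(self):
        rng = np.random.default_rng(3)
        a = rng.normal(50, 10, size=(5000, 5))
        b = rng.normal(50, 10, size=(5000, 6))
        mat = matrix_from_arrays(a, b)
        res = loci_t_test(mat, "Con", "UN")
        select_candidates(res)
        corr = permutation_correction(mat, "Con", "UN", res,
                                      n_perm=200, seed=2)
        frac = (res["p_value"] <= corr.threshold_p).mean()
        assert frac == pytest.approx(0.025, abs=0.008)

    def test_never_promotes_noncandidate(self, small_matrix):
        res = loci_t_test(small_matrix, "Con", "UN")
        cands = select_candidates(res)
        corr = permutation_correction(small_matrix, "Con", "UN", res,
                                      n_perm=100, seed=4)
        assert set(corr.corrected.index) == set(cands["locus_id"])

    def test_warns_when_fewer_distinct_assignments(self):
        rng = np.random.default_rng(5)
        a = rng.normal(50, 10, size=(50, 2))
        b = rng.normal(50, 10, size=(50, 2))
        mat = matrix_from_arrays(a, b)
        res = loci_t_test(mat, "Con", "UN")
        select_candidates(res)
        with pytest.warns(UserWarning, match="distinct"):
            permutation_correction(mat, "Con", "UN", res, n_perm=100, seed=6)

    def test_determinism(self, small_matrix):
        res = loci_t_test(small_matrix, "Con", "UN")
        select_candidates(res)
        c1 = permutation_correction(small_matrix, "Con", "UN", res,
                                    n_perm=100, seed=7)
        c2 = permutation_correction(small_matrix, "Con", "UN", res,
                                    n_perm=100, seed=7)
        assert c1.threshold_p == c2.threshold_p


class TestPower:
    def test_null_power_equals_alpha(self):
        pe = power_simulation(delta=0.0, alpha=0.05, n_sim=2000, seed=8)
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert pe.power == pytest.approx(0.05, abs=3 * se)

    def test_saturated_effect(self):
        pe = power_simulation(delta=30.0, sd=1.0, n_sim=500, seed=9)
        assert pe.power == 1.0

    def test_simulation_matches_noncentral_t_oracle(self):
        # frozen analytic values: power(5v5)=0.774705, power(5v6)=0.849846
        assert analytic_power(5, 10, 30, 0.005) == pytest.approx(
            0.774705, abs=1e-6)
        assert analytic_power(5, 10, 30, 0.005, 6) == pytest.approx(
            0.849846, abs=1e-6)
        pe = power_simulation(n_per_group=5, sd=10, delta=30, alpha=0.005,
                              n_sim=1000, seed=10)
        assert pe.power == pytest.approx(pe.analytic_power, abs=3 * pe.mc_se)

    def test_mc_se_definition(self):
        pe = power_simulation(n_sim=1000, seed=11)
        assert pe.mc_se == pytest.approx(
            np.sqrt(pe.power * (1 - pe.power) / 1000))


class TestClusterLoci:
    def test_group_structure_recovered(self):
        lo = np.full((20, 5), 20.0)
        hi = np.full((20, 6), 80.0)
        rng = np.random.default_rng(12)
        mat = matrix_from_arrays(lo + rng.normal(0, 1, lo.shape),
                                 hi + rng.normal(0, 1, hi.shape))
        z, order = cluster_loci(mat, mat.scores.index, by="samples")
        two = fcluster(z, 2, criterion="maxclust")
        labels = [mat.groups[s] for s in mat.samples]
        # the 2-cut must separate the groups exactly
        assert len({c for c, g in zip(two, labels) if g == "Con"}) == 1
        assert len({c for c, g in zip(two, labels) if g == "UN"}) == 1

    def test_identical_samples_zero_heights(self):
        mat = matrix_from_arrays(np.full((10, 3), 40.0), np.full((10, 3), 40.0))
        z, _ = cluster_loci(mat, mat.scores.index, by="samples")
        assert np.allclose(z[:, 2], 0.0)

    def test_leaf_order_is_permutation(self, small_matrix):
        ids = list(small_matrix.scores.index[:50])
        _, order = cluster_loci(small_matrix, ids, by="samples")
        assert sorted(order) == sorted(small_matrix.samples)

    def test_single_sample_trivial_tree(self):
        mat = matrix_from_arrays(np.full((5, 1), 40.0), np.empty((5, 0)))
        z, order = cluster_loci(mat, mat.scores.index, by="samples")
        assert z.shape == (0, 4)
        assert order == ["Con0"]
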