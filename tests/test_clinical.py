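"""Clinicopathological association, clustering, and survival statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnamcr.clinical import (
    age_correlation,
    cluster_samples,
    gain_cooccurrence,
    km_logrank,
    lauren_association,
    size_stratified_platform_comparison,
)
from cnamcr.clinical import test_2x2 as two_by_two

from oracles import fisher_exact_oracle, logrank_permutation_p


class TestTwoByTwo:
    def test_perfect_separation_fisher(self):
        # expected counts are 2.5 < 5, so Fisher applies: p = 2/252
        test, p = two_by_two([[5, 0], [0, 5]])
        assert test == "fisher"
        assert p == pytest.approx(2 / 252)

    def test_identical_distributions_not_significant(self):
        test, p = two_by_two([[20, 20], [20, 20]])
        assert test == "chi-square"
        assert p == pytest.approx(1.0)

    def test_empty_margin_gives_missing_p(self):
        with pytest.warns(UserWarning):
            test, p = two_by_two([[0, 0], [3, 4]])
        assert np.isnan(p)

    @pytest.mark.parametrize("seed", range(10))
    def test_fisher_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            tab = rng.integers(0, 11, (2, 2))
            if tab.sum() <= 40 and tab.sum(0).min() > 0 and tab.sum(1).min() > 0:
                break
        _, p_scipy = stats.fisher_exact(tab, alternative="two-sided")
        assert p_scipy == pytest.approx(fisher_exact_oracle(tab), abs=1e-10)


class TestLaurenAssociation:
    def test_mixed_type_excluded_and_tables_counted(self):
        status = {"g": {"a": True, "b": True, "c": False, "d": False, "e": True}}
        types = {"a": "diffuse", "b": "intestinal", "c": "diffuse",
                 "d": "intestinal", "e": "mixed"}
        out = lauren_association(status, types)
        row = out.iloc[0]
        assert row[["n_cna_diffuse", "n_cna_intestinal",
                    "n_no_cna_diffuse", "n_no_cna_intestinal"]].sum() == 4

    def test_identical_distribution_p_near_one(self):
        status = {"g": {f"s{i}": i % 2 == 0 for i in range(40)}}
        types = {f"s{i}": ("diffuse" if i < 20 else "intestinal") for i in range(40)}
        out = lauren_association(status, types)
        assert out.iloc[0]["p"] > 0.9


class TestGainCooccurrence:
    def test_identical_vectors_minimal_p(self):
        a = np.array([True] * 10 + [False] * 10)
        p = gain_cooccurrence(a, a)
        tab = [[10, 0], [0, 10]]
        assert p == pytest.approx(fisher_exact_oracle(tab))

    def test_null_pvalues_valid(self):
        # the discrete two-sided Fisher p is super-uniform under the null:
        # P(p <= x) never exceeds x by more than sampling error, and the
        # rejection rate at alpha = 0.05 is controlled
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(1000):
            a = rng.random(30) < 0.5
            b = rng.random(30) < 0.5
            p = gain_cooccurrence(a, b)
            if np.isfinite(p):
                ps.append(min(p, 1.0))
        ps = np.sort(ps)
        ecdf_excess = np.max(np.arange(1, len(ps) + 1) / len(ps) - ps)
        assert ecdf_excess <= 0.05
        assert np.mean(ps < 0.05) <= 0.06

    def test_degenerate_margin_missing(self):
        with pytest.warns(UserWarning):
            p = gain_cooccurrence([True, True, True], [True, False, True])
        assert np.isnan(p)


class TestAgeCorrelation:
    def test_bonferroni_rule(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(40, 80, 30)
        genes = {"g": 0.02 * ages + rng.normal(0, 0.3, 30)}
        out = age_correlation(genes, ages, m_genes=15)
        row = out.iloc[0]
        assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p_raw"] * 15))

    def test_bonferroni_capped_and_monotone(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(40, 80, 20)
        genes = {f"g{i}": rng.normal(0, 0.3, 20) for i in range(5)}
        out = age_correlation(genes, ages)
        assert (out["p_bonferroni"] <= 1.0).all()
        srt = out.sort_values("p_raw")
        assert srt["p_bonferroni"].is_monotonic_increasing

    def test_perfect_linear_r_one(self):
        ages = np.arange(20.0, 50.0)
        out = age_correlation({"g": ages * 0.1}, ages)
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_constant_vector_missing(self):
        out = age_correlation({"g": np.zeros(10)}, np.arange(10.0))
        assert np.isnan(out.iloc[0]["r"])


class TestClusterSamples:
    def _matrix(self):
        rng = np.random.default_rng(5)
        block1 = np.tile([1.0, 1.0, 0.0, 0.0], (10, 1))
        block2 = np.tile([0.0, 0.0, 0.0, 0.0], (10, 1))
        mat = np.vstack([block1, block2])
        return pd.DataFrame(mat, index=[f"s{i:02d}" for i in range(20)],
                            columns=["g8q24_a", "g8q24_b", "g20q_a", "g4"])

    def test_identical_rows_merge_first_at_height_zero(self):
        df = pd.DataFrame([[1.0, 0.0], [1.0, 0.0], [5.0, 5.0]],
                          index=["a", "b", "c"], columns=["x", "y"])
        out = cluster_samples(df)
        assert out["linkage"][0, 2] == 0.0

    def test_planted_two_block_partition_recovered(self):
        out = cluster_samples(self._matrix(), k=2)
        labels = out["clusters"]
        block1 = {labels[f"s{i:02d}"] for i in range(10)}
        block2 = {labels[f"s{i:02d}"] for i in range(10, 20)}
        assert len(block1) == 1 and len(block2) == 1 and block1 != block2

    def test_input_order_invariance(self):
        df = self._matrix()
        shuffled = df.sample(frac=1.0, random_state=3)
        a = cluster_samples(df, k=2)
        b = cluster_samples(shuffled, k=2)
        assert a["leaf_order"] == b["leaf_order"]
        assert a["clusters"] == b["clusters"]

    def test_missing_values_imputed_with_warning(self):
        df = self._matrix()
        df.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="imputed"):
            out = cluster_samples(df)
        assert out["imputed"]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame([[1.0]], index=["a"]))

    def test_newick_renders_all_leaves(self):
        out = cluster_samples(self._matrix())
        for sid in self._matrix().index:
            assert sid in out["newick"]


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [3, 5, 7, 3, 5, 7]
        e = [1, 1, 1, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        out = km_logrank(g, t, e)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-10)
        assert out["p"] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        # hand-computed log-rank: O-E = 1.85, Var = 0.6775, chi2 ~ 5.05
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 1, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        out = km_logrank(g, t, e)
        assert out["statistic"] == pytest.approx((3 - 1.15) ** 2 / 0.6775, rel=1e-3)
        assert out["p"] < 0.05

    def test_matches_permutation_approximation(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 14).round(1)
        e = (rng.random(14) < 0.8).astype(int)
        g = np.array(["a"] * 7 + ["b"] * 7)
        out = km_logrank(g, t, e)
        p_perm, _ = logrank_permutation_p(t, e, g, n_perm=1000, seed=0)
        assert out["p"] == pytest.approx(p_perm, abs=0.06)

    def test_all_censored_missing_p(self):
        with pytest.warns(UserWarning):
            out = km_logrank(["a", "a", "b", "b"], [1, 2, 3, 4], [0, 0, 0, 0])
        assert np.isnan(out["p"])

    def test_single_sample_group_warns(self):
        with pytest.warns(UserWarning, match="single"):
            out = km_logrank(["a", "b", "b", "b"], [1, 2, 3, 4], [1, 1, 1, 1])
        assert np.isfinite(out["p"])


class _FakeCall:
    def __init__(self, length, direction="loss"):
        self.length = length
        self.direction = direction


class TestSizeStratifiedComparison:
    def test_identical_call_sets_not_significant(self):
        calls = [_FakeCall(l) for l in [2_000] * 30 + [20_000] * 30 + [200_000] * 30]
        out = size_stratified_platform_comparison(calls, list(calls))
        assert (out.loc[out["test"] != "skipped", "p"] > 0.9).all()

    def test_extra_small_losses_significant_only_in_small_bin(self):
        base = [_FakeCall(l) for l in [20_000] * 60 + [200_000] * 60]
        platform1 = base + [_FakeCall(2_000) for _ in range(15)]
        platform2 = list(base)
        out = size_stratified_platform_comparison(platform1, platform2).set_index("bin")
        assert out.loc["1000-5000", "p"] < 0.05
        others = out.drop(index="1000-5000")
        assert (others.loc[others["test"] != "skipped", "p"] > 0.05).all()

    def test_empty_bins_rejected(self):
        with pytest.raises(ValueError):
            size_stratified_platform_comparison([_FakeCall(1)], [_FakeCall(1)], bins=[])
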