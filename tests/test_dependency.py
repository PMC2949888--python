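import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neffnet import (
    block_permutation_test,
    correlated_experiment_pairs,
    group_v1_by_factor,
    leading_eigenvector,
    project_fcp,
    sample_correlations,
)
from neffnet.dependency import EigenSummary
from neffnet.effective_size import total_correlation_sq
from neffnet.io import CompendiumMetadata, ExpressionMatrix
from neffnet.trni import bh_select, fisher_z
from neffnet import double_standardize, synthdata as sd


class TestLeadingEigenvector:
    def test_two_by_two_closed_form(self):
        eig = leading_eigenvector(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert eig.lambda1 == pytest.approx(1.5)
        np.testing.assert_allclose(eig.v1, [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12)

    def test_identity_warns_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            leading_eigenvector(np.eye(4))

    def test_sign_convention_largest_component_positive(self):
        C = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        eig = leading_eigenvector(C)
        assert eig.v1[np.argmax(np.abs(eig.v1))] > 0

    def test_negating_data_leaves_v1_unchanged(self, make_std_matrix):
        Xs = make_std_matrix(30, 8, seed=2)
        _, delta = sample_correlations(Xs)
        neg = ExpressionMatrix(-Xs.values, Xs.gene_ids, Xs.experiment_ids, standardized=True)
        _, delta_neg = sample_correlations(neg)
        a = leading_eigenvector(delta)
        b = leading_eigenvector(delta_neg)
        np.testing.assert_allclose(a.v1, b.v1, atol=1e-12)
        assert np.linalg.norm(a.v1) == pytest.approx(1.0)


class TestBlockPermutationTest:
    def test_maximal_separation_matches_enumeration(self):
        # perfectly block-separated values: the observed statistic is the
        # maximum attainable, reached by exactly 2 of the C(6,3)=20 distinct
        # assignments (all +1 in one block or the other), so the exact
        # permutation p-value is 2/20 = 0.1
        values = np.array([1.0, 1, 1, -1, -1, -1])
        blocks = np.array(list("AAABBB"))
        stat, p = block_permutation_test(values, blocks, n_perm=1999, seed=0)

        def bss(v):
            g = v.mean()
            return sum(3 * (v[idx].mean() - g) ** 2 for idx in (slice(0, 3), slice(3, 6)))

        stats_all = [bss(np.array(perm)) for perm in itertools.permutations(values)]
        assert stat == pytest.approx(max(stats_all))
        exact_p = sum(s >= stat - 1e-12 for s in stats_all) / len(stats_all)
        assert exact_p == pytest.approx(0.1)
        assert p == pytest.approx(exact_p, abs=0.03)

    def test_constant_values_give_p_one(self):
        stat, p = block_permutation_test(np.ones(6), list("AAABBB"), n_perm=200, seed=1)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_null_values_not_significant(self):
        rng = np.random.default_rng(100)
        values = rng.standard_normal(40)
        blocks = np.repeat(list("ABCD"), 10)
        _, p = block_permutation_test(values, blocks, n_perm=2000, seed=7)
        assert p > 0.05

    def test_single_block_errors(self):
        with pytest.raises(ValueError, match="2 blocks"):
            block_permutation_test([1.0, 2.0], ["A", "A"], n_perm=10, seed=0)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            block_permutation_test([1.0, 2.0], ["A", "B"], n_perm=10)

    def test_detects_planted_block_structure(self):
        # block-structured experiment dependence aligned with projects
        X, _, _, meta = sd.matrix_normal_sample(
            sd.GeneratorSpec(p=300, n=40, sigma_spec=sd.identity(),
                             delta_spec=sd.blocks([10] * 4, rho=0.5), seed=3)
        )
        Xs, _ = double_standardize(X)
        _, delta = sample_correlations(Xs)
        eig = leading_eigenvector(delta, Xs.experiment_ids)
        _, p = block_permutation_test(eig.v1, meta.project_of(Xs.experiment_ids),
                                      n_perm=999, seed=5)
        assert p < 0.01


class TestCorrelatedPairs:
    def test_duplicated_experiment_is_top_pair(self, make_matrix):
        X = make_matrix(80, 10, seed=4)
        vals = np.column_stack([X.values, X.values[:, 0] + 1e-9])
        X2 = ExpressionMatrix(vals, X.gene_ids, X.experiment_ids + ["e_dup"])
        Xs, _ = double_standardize(X2)
        pairs = correlated_experiment_pairs(Xs, q=0.1)
        top = pairs.sort_values("p").iloc[0]
        assert {top["exp_i"], top["exp_j"]} == {"e0", "e_dup"}
        assert top["significant"]

    def test_matches_brute_force_on_toy(self, make_std_matrix):
        Xs = make_std_matrix(50, 5, seed=8)
        pairs = correlated_experiment_pairs(Xs, q=0.2)
        sigma, delta = sample_correlations(Xs)
        p_genes = Xs.n_genes
        alpha = total_correlation_sq(sigma)
        p_eff = p_genes / (1 + (p_genes - 1) * alpha)
        d = np.diag(delta)
        expected = []
        for a in range(5):
            for b in range(a + 1, 5):
                r = delta[a, b] / np.sqrt(d[a] * d[b])
                z = 0.5 * np.log((1 + r) / (1 - r))
                expected.append(2 * stats.norm.sf(abs(z) * np.sqrt(p_eff - 3)))
        reject, _ = bh_select(np.array(expected), 0.2)
        np.testing.assert_allclose(pairs["p"].to_numpy(), expected, atol=1e-12)
        assert list(pairs["significant"]) == list(reject)

    def test_null_data_yields_few_pairs(self):
        X, _, _, _ = sd.matrix_normal_sample(
            sd.GeneratorSpec(p=400, n=15, sigma_spec=sd.identity(),
                             delta_spec=sd.identity(), seed=17)
        )
        Xs, _ = double_standardize(X)
        pairs = correlated_experiment_pairs(Xs, q=0.1)
        n_pairs = 15 * 14 // 2
        assert pairs["significant"].sum() <= 0.1 * n_pairs

    def test_pvalues_stable_under_column_permutation(self, make_std_matrix):
        Xs = make_std_matrix(40, 6, seed=10)
        rng = np.random.default_rng(1)
        perm = rng.permutation(6)
        Xp = ExpressionMatrix(Xs.values[:, perm], Xs.gene_ids,
                              [Xs.experiment_ids[i] for i in perm], standardized=True)
        a = np.sort(correlated_experiment_pairs(Xs, q=0.1)["p"].to_numpy())
        b = np.sort(correlated_experiment_pairs(Xp, q=0.1)["p"].to_numpy())
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_bh_monotone_in_q(self, make_std_matrix):
        Xs = make_std_matrix(60, 8, seed=14)
        strict = correlated_experiment_pairs(Xs, q=0.05)
        loose = correlated_experiment_pairs(Xs, q=0.10)
        sig_strict = set(map(tuple, strict[strict.significant][["exp_i", "exp_j"]].values))
        sig_loose = set(map(tuple, loose[loose.significant][["exp_i", "exp_j"]].values))
        assert sig_strict <= sig_loose

    def test_peff_le_three_errors(self):
        # two near-duplicate genes -> alpha^2 ~ 1 -> p_eff ~ 1
        M = np.array([[1.0, -1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, 1.0]])
        X = ExpressionMatrix(M, list("abcd"), ["e1", "e2"], standardized=True)
        with pytest.raises(ValueError, match="p_eff"):
            correlated_experiment_pairs(X)


class TestProjectFCP:
    def _pairs(self, sig_pairs, ids):
        rows = []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                rows.append({"exp_i": a, "exp_j": b,
                             "significant": {a, b} in sig_pairs})
        return pd.DataFrame(rows)

    def _meta(self, ids, project):
        return CompendiumMetadata(pd.DataFrame({"project_id": [project] * len(ids)}, index=ids))

    def test_no_significant_pairs_gives_zero(self):
        ids = ["a", "b", "c", "d"]
        fcp = project_fcp(self._pairs([], ids), self._meta(ids, "P1"))
        assert fcp.loc[0, "fcp"] == 0.0

    def test_all_pairs_significant_gives_one(self):
        ids = ["a", "b", "c", "d"]
        sig = [set(x) for x in itertools.combinations(ids, 2)]
        fcp = project_fcp(self._pairs(sig, ids), self._meta(ids, "P1"))
        assert fcp.loc[0, "fcp"] == 1.0

    def test_partial_count(self):
        ids = ["a", "b", "c", "d"]
        fcp = project_fcp(self._pairs([{"a", "b"}, {"c", "d"}], ids), self._meta(ids, "P1"))
        assert fcp.loc[0, "fcp"] == pytest.approx(2 / 6)

    def test_undersized_projects_omitted(self):
        ids = ["a", "b", "c", "d", "e"]
        meta = CompendiumMetadata(pd.DataFrame(
            {"project_id": ["P1"] * 4 + ["P2"]}, index=ids))
        fcp = project_fcp(self._pairs([], ids), meta, min_size=4)
        assert list(fcp["project_id"]) == ["P1"]


class TestGroupV1:
    def _setup(self):
        eig = EigenSummary(v1=np.array([0.5, -0.2, 0.3, 0.1]), lambda1=2.0,
                           experiment_ids=["e1", "e2", "e3", "e4"])
        meta = CompendiumMetadata(pd.DataFrame(
            {"project_id": ["P1"] * 4,
             "growth_phase": ["log", "late log", "stationary", "biofilm"]},
            index=["e1", "e2", "e3", "e4"]))
        return eig, meta

    def test_two_group_map_conserves_n(self):
        eig, meta = self._setup()
        groups = group_v1_by_factor(eig, meta, "growth_phase",
                                    {"log": "early", "late log": "late",
                                     "stationary": "late", "biofilm": "late"})
        assert sum(len(v) for v in groups.values()) == 4
        assert len(groups["late"]) == 3

    def test_unmapped_state_goes_to_other_with_warning(self):
        eig, meta = self._setup()
        with pytest.warns(UserWarning, match="other"):
            groups = group_v1_by_factor(eig, meta, "growth_phase", {"log": "early"})
        assert len(groups["other"]) == 3

    def test_missing_factor_names_available(self):
        eig, meta = self._setup()
        with pytest.raises(KeyError, match="growth_phase"):
            group_v1_by_factor(eig, meta, "media_type")

    def test_planted_blocks_separate_group_means(self):
        # unequal block sizes so the leading eigenvalue is non-degenerate
        # and v1 concentrates on the larger block
        X, _, _, meta = sd.matrix_normal_sample(
            sd.GeneratorSpec(p=400, n=20, sigma_spec=sd.identity(),
                             delta_spec=sd.blocks([12, 8], rho=0.7), seed=9)
        )
        meta.table["half"] = ["first"] * 12 + ["second"] * 8
        Xs, _ = double_standardize(X)
        _, delta = sample_correlations(Xs)
        eig = leading_eigenvector(delta, Xs.experiment_ids)
        groups = group_v1_by_factor(eig, meta, "half")
        m1, m2 = np.mean(groups["first"]), np.mean(groups["second"])
        assert abs(m1 - m2) > 0.1
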