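import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoniche.errors import AlignmentError, ConsistencyError, DataError, TreeError
from thermoniche.phylo_comparative import (
    DistanceMatrix,
    _lambda_profile_loglik_factory,
    blombergs_k,
    fit_pagels_lambda,
    geographic_distance_matrix,
    is_ultrametric,
    k_permutation_test,
    lambda_transform,
    mantel_test,
    p_distance_matrix,
    phylo_vcv,
    read_tree,
    root_to_tip_depths,
    ultrametricize_pl,
)
from thermoniche.synthetic_data import simulate_trait, simulate_tree


class TestPhyloVcv:
    def test_two_tip_tree(self):
        tree = read_tree("(A:1.0,B:1.0);", from_path=False)
        cov = phylo_vcv(tree)
        assert cov.labels == ("A", "B")
        np.testing.assert_allclose(cov.matrix, [[1, 0], [0, 1]])

    def test_three_tip_hand_computed(self, three_tip_tree):
        cov = phylo_vcv(three_tip_tree)
        order = {l: i for i, l in enumerate(cov.labels)}
        expect = {("A", "A"): 2, ("B", "B"): 2, ("C", "C"): 2,
                  ("A", "B"): 1, ("A", "C"): 0, ("B", "C"): 0}
        for (a, b), v in expect.items():
            assert cov.matrix[order[a], order[b]] == pytest.approx(v)
            assert cov.matrix[order[b], order[a]] == pytest.approx(v)

    def test_symmetric_nonnegative(self):
        tree = simulate_tree(16, seed=5)
        cov = phylo_vcv(tree)
        np.testing.assert_allclose(cov.matrix, cov.matrix.T)
        assert np.all(cov.matrix >= 0)

    def test_warns_on_non_ultrametric(self, nonclock_tree):
        with pytest.warns(UserWarning, match="not ultrametric"):
            phylo_vcv(nonclock_tree)

    def test_positive_semidefinite(self):
        tree = simulate_tree(32, seed=9)
        cov = phylo_vcv(tree)
        assert np.linalg.eigvalsh(cov.matrix).min() > -1e-10


class TestUltrametricizePL:
    def test_clocklike_tree_is_fixed_point(self, three_tip_tree):
        out = ultrametricize_pl(three_tip_tree, smoothing=0.1)
        depths = root_to_tip_depths(out)
        assert np.ptp(list(depths.values())) < 1e-9
        # rates all equal on a clocklike input
        assert np.ptp(out.pl_rates) < 1e-4 * out.pl_rates.mean()

    def test_output_is_ultrametric(self, nonclock_tree):
        out = ultrametricize_pl(nonclock_tree, smoothing=0.1)
        d = np.array(list(root_to_tip_depths(out).values()))
        assert np.ptp(d) < 1e-6 * d.max()

    def test_root_age_is_one(self, nonclock_tree):
        out = ultrametricize_pl(nonclock_tree, smoothing=0.1)
        assert max(root_to_tip_depths(out).values()) == pytest.approx(1.0, abs=1e-9)

    def test_topology_preserved(self):
        tree = simulate_tree(12, seed=2)
        rng = np.random.default_rng(0)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= float(rng.uniform(0.3, 3.0))
        before = {frozenset(l.taxon.label for l in nd.leaf_iter())
                  for nd in tree.preorder_node_iter()}
        out = ultrametricize_pl(tree, smoothing=0.1)
        after = {frozenset(l.taxon.label for l in nd.leaf_iter())
                 for nd in out.preorder_node_iter()}
        assert before == after

    def test_three_tip_matches_brute_force(self, nonclock_tree):
        """Grid-search oracle over the single free node age + inner rate opt."""
        from scipy.optimize import minimize

        smoothing = 0.1
        b = {"A": 0.8, "B": 1.2, "AB": 0.5, "C": 1.9}

        def objective(a, log_r):
            rA, rB, rAB, rC = np.exp(log_r)
            t = {"A": a, "B": a, "AB": 1 - a, "C": 1.0}
            r = {"A": rA, "B": rB, "AB": rAB, "C": rC}
            ll = sum(b[e] * math.log(r[e] * t[e]) - r[e] * t[e] for e in b)
            pen = (rA - rAB) ** 2 + (rB - rAB) ** 2 + np.var([rAB, rC])
            return ll - smoothing * pen

        best = -np.inf
        for a in np.linspace(0.02, 0.98, 97):
            res = minimize(lambda lr: -objective(a, lr), np.zeros(4), method="BFGS")
            best = max(best, -res.fun)

        out = ultrametricize_pl(nonclock_tree, smoothing=smoothing)
        assert out.pl_objective == pytest.approx(best, abs=1e-3)

    def test_unrooted_input_rejected(self):
        tree = read_tree("(A:1,B:1,C:1);", from_path=False)
        with pytest.raises(TreeError, match="unrooted"):
            ultrametricize_pl(tree)

    def test_zero_length_branch_floored(self):
        tree = read_tree("((A:0.0,B:1.0):0.5,C:1.5);", from_path=False)
        with pytest.warns(UserWarning, match="floored"):
            out = ultrametricize_pl(tree, smoothing=0.1)
        assert is_ultrametric(out)


class TestPagelsLambda:
    def test_lambda_transform_endpoints(self):
        tree = simulate_tree(10, seed=1)
        C = phylo_vcv(tree).matrix
        np.testing.assert_allclose(lambda_transform(C, 1.0), C)
        C0 = lambda_transform(C, 0.0)
        np.testing.assert_allclose(C0, np.diag(np.diag(C)))

    def test_loglik_at_mle_dominates_endpoints(self):
        tree = simulate_tree(24, seed=4)
        trait = simulate_trait(tree, 1.0, 0.0, 0.7, seed=8)
        cov = phylo_vcv(tree)
        y = np.array([trait[l] for l in cov.labels])
        f = _lambda_profile_loglik_factory(cov.matrix, y)
        est = fit_pagels_lambda(tree, trait)
        assert est.log_likelihood >= f(0.0)[0] - 1e-8
        assert est.log_likelihood >= f(1.0)[0] - 1e-8

    def test_profile_likelihood_matches_mvn_density(self):
        from scipy.stats import multivariate_normal

        tree = simulate_tree(12, seed=6)
        trait = simulate_trait(tree, 1.0, 2.0, 0.6, seed=7)
        cov = phylo_vcv(tree)
        y = np.array([trait[l] for l in cov.labels])
        f = _lambda_profile_loglik_factory(cov.matrix, y)
        for lam in (0.0, 0.25, 0.9, 1.0):
            logl, s2, a = f(lam)
            V = s2 * lambda_transform(cov.matrix, lam)
            ref = multivariate_normal(mean=np.full(y.size, a), cov=V).logpdf(y)
            assert logl == pytest.approx(ref, rel=1e-9)

    def test_bm_trait_gives_high_lambda(self):
        tree = simulate_tree(64, seed=10)
        vals = [fit_pagels_lambda(tree, simulate_trait(tree, 1.0, 0.0, 1.0, seed=s)).statistic
                for s in range(20)]
        assert np.mean(vals) > 0.85

    def test_independent_trait_gives_low_lambda(self):
        tree = simulate_tree(64, seed=10)
        vals = [fit_pagels_lambda(tree, simulate_trait(tree, 1.0, 0.0, 0.0, seed=s)).statistic
                for s in range(20)]
        assert np.mean(vals) < 0.15

    def test_constant_trait_errors(self, three_tip_tree):
        with pytest.raises(DataError):
            fit_pagels_lambda(three_tip_tree, {"A": 1.0, "B": 1.0, "C": 1.0})

    def test_estimate_in_unit_interval_with_valid_p(self):
        tree = simulate_tree(16, seed=13)
        trait = simulate_trait(tree, 1.0, 0.0, 0.5, seed=14)
        est = fit_pagels_lambda(tree, trait)
        assert 0.0 <= est.statistic <= 1.0
        assert 0.0 < est.p_value <= 1.0


class TestBlombergsK:
    def test_hand_assembled_three_tip(self):
        # C written down by hand for ((A:1,B:1):1,C:2)
        C = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        y = np.array([1.0, 2.0, 4.0])
        n = 3
        Ci = np.linalg.inv(C)
        a0 = (np.ones(n) @ Ci @ y) / (np.ones(n) @ Ci @ np.ones(n))
        d = y - a0
        mse0 = d @ d / (n - 1)
        mse = d @ Ci @ d / (n - 1)
        expected_ratio = (np.trace(C) - n / Ci.sum()) / (n - 1)
        k_oracle = (mse0 / mse) / expected_ratio

        tree = read_tree("((A:1.0,B:1.0):1.0,C:2.0);", from_path=False)
        est = blombergs_k(tree, {"A": 1.0, "B": 2.0, "C": 4.0})
        assert est.statistic == pytest.approx(k_oracle, rel=1e-12)

    def test_bm_calibration_small(self):
        tree = simulate_tree(64, seed=5)
        ks = [blombergs_k(tree, simulate_trait(tree, 1.0, 0.0, 1.0, seed=s)).statistic
              for s in range(60)]
        assert 0.8 < np.mean(ks) < 1.2

    def test_shuffled_trait_reduces_k(self):
        tree = simulate_tree(64, seed=5)
        trait = simulate_trait(tree, 1.0, 0.0, 1.0, seed=77)
        labels = list(trait)
        rng = np.random.default_rng(1)
        k_obs = blombergs_k(tree, trait).statistic
        shuffled_ks = []
        for _ in range(10):
            vals = rng.permutation([trait[l] for l in labels])
            shuffled_ks.append(
                blombergs_k(tree, dict(zip(labels, vals))).statistic)
        assert np.mean(shuffled_ks) < k_obs

    @given(scale=st.floats(0.1, 10), shift=st.floats(-100, 100))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, scale, shift):
        tree = simulate_tree(16, seed=21)
        trait = simulate_trait(tree, 1.0, 0.0, 1.0, seed=22)
        k1 = blombergs_k(tree, trait).statistic
        k2 = blombergs_k(tree, {l: scale * v + shift for l, v in trait.items()}).statistic
        assert k2 == pytest.approx(k1, rel=1e-9)


class TestKPermutationTest:
    def test_p_above_add_one_bound(self):
        tree = simulate_tree(16, seed=2)
        trait = simulate_trait(tree, 1.0, 0.0, 1.0, seed=3)
        p = k_permutation_test(tree, trait, n_perm=199, seed=0)
        assert p >= 1 / 200

    def test_deterministic_given_seed(self):
        tree = simulate_tree(16, seed=2)
        trait = simulate_trait(tree, 1.0, 0.0, 1.0, seed=3)
        p1 = k_permutation_test(tree, trait, n_perm=199, seed=42)
        p2 = k_permutation_test(tree, trait, n_perm=199, seed=42)
        assert p1 == p2

    def test_rejects_small_n_perm(self, three_tip_tree):
        with pytest.raises(DataError):
            k_permutation_test(three_tip_tree, {"A": 1, "B": 2, "C": 3}, n_perm=10)


class TestPDistance:
    def test_identical_sequences(self):
        d = p_distance_matrix({"a": "ACGT", "b": "ACGT"})
        assert d.matrix[0, 1] == 0.0

    def test_one_in_four_differs(self):
        d = p_distance_matrix({"a": "ACGT", "b": "AGGT"})
        assert d.matrix[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_of_gaps(self):
        d = p_distance_matrix({"a": "AC-T", "b": "ACGT"})
        assert d.matrix[0, 1] == 0.0

    def test_ambiguity_codes_are_missing(self):
        # N and R excluded; 1 difference over 3 comparable sites
        d = p_distance_matrix({"a": "ANRAT", "b": "ACGGT"})
        assert d.matrix[0, 1] == pytest.approx(1 / 3)

    def test_case_insensitive(self):
        d = p_distance_matrix({"a": "acgt", "b": "ACGT"})
        assert d.matrix[0, 1] == 0.0

    def test_unequal_lengths_error(self):
        with pytest.raises(AlignmentError):
            p_distance_matrix({"a": "ACGT", "b": "ACG"})

    def test_no_comparable_sites_error(self):
        with pytest.raises(AlignmentError, match="'a'.*'b'"):
            p_distance_matrix({"a": "AC--", "b": "--GT"})


class TestGeographicDistance:
    def test_identical_coordinates(self):
        d = geographic_distance_matrix({"a": (10.0, 20.0), "b": (10.0, 20.0)})
        assert d.matrix[0, 1] == 0.0

    def test_antipodal_closed_form(self):
        d = geographic_distance_matrix({"a": (0.0, 0.0), "b": (0.0, 180.0)})
        assert d.matrix[0, 1] == pytest.approx(math.pi * 6371.0, rel=1e-9)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        coords = {f"s{i}": (rng.uniform(-80, 80), rng.uniform(-180, 180)) for i in range(8)}
        d = geographic_distance_matrix(coords)
        np.testing.assert_allclose(d.matrix, d.matrix.T)

    def test_out_of_range_coordinates(self):
        with pytest.raises(DataError):
            geographic_distance_matrix({"a": (95.0, 0.0), "b": (0.0, 0.0)})


class TestMantel:
    def fixed_matrices(self, n=10, seed=0):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(seed)
        labels = tuple(f"s{i}" for i in range(n))
        a = squareform(pdist(rng.normal(size=(n, 2))))
        b = squareform(pdist(rng.normal(size=(n, 2))))
        return DistanceMatrix(labels, a), DistanceMatrix(labels, b)

    def test_self_correlation_is_one(self):
        d1, _ = self.fixed_matrices()
        res = mantel_test(d1, d1, n_perm=99, seed=0)
        assert res["r"] == pytest.approx(1.0)

    def test_p_within_add_one_bounds(self):
        d1, d2 = self.fixed_matrices()
        res = mantel_test(d1, d2, n_perm=199, seed=1)
        assert 1 / 200 <= res["p"] <= 1.0

    def test_deterministic_given_seed(self):
        d1, d2 = self.fixed_matrices()
        assert mantel_test(d1, d2, 199, seed=5) == mantel_test(d1, d2, 199, seed=5)

    def test_label_mismatch_errors(self):
        d1, d2 = self.fixed_matrices()
        relabeled = DistanceMatrix(tuple(reversed(d2.labels)), d2.matrix)
        with pytest.raises(ConsistencyError):
            mantel_test(d1, relabeled, 99, seed=0)

    def test_invariant_under_common_relabeling(self):
        d1, d2 = self.fixed_matrices()
        perm = np.random.default_rng(3).permutation(len(d1.labels))
        l2 = tuple(d1.labels[i] for i in perm)
        r1 = mantel_test(d1, d2, 99, seed=0)["r"]
        d1p = DistanceMatrix(l2, d1.matrix[np.ix_(perm, perm)])
        d2p = DistanceMatrix(l2, d2.matrix[np.ix_(perm, perm)])
        r2 = mantel_test(d1p, d2p, 99, seed=0)["r"]
        assert r2 == pytest.approx(r1, rel=1e-12)


class TestDistanceMatrixValidation:
    def test_rejects_asymmetric(self):
        with pytest.raises(DataError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(DataError):
            DistanceMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_rejects_negative(self):
        with pytest.raises(DataError):
            DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))
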