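"""Newick handling, Brownian covariance, PGLS with Pagel's lambda."""

import numpy as np
import pytest

from spliceratio import (
    PGLS,
    parse_newick,
    pgls_fit,
    phylo_covariance,
    prune_to,
    simulate_tree_traits,
    tip_labels,
    write_newick,
)
from spliceratio.errors import SpliceRatioError

THREE_TAXON = "((A:1,B:1):1,C:2);"


def _patristic(tree):
    C, labels = phylo_covariance(tree, lam=1.0)
    d = np.diag(C)
    return labels, d[:, None] + d[None, :] - 2 * C


class TestNewick:
    def test_parse_basic(self):
        tree = parse_newick(THREE_TAXON)
        assert sorted(tip_labels(tree)) == ["A", "B", "C"]
        assert len(tree.seed_node.child_nodes()) == 2

    def test_missing_lengths_defaulted_with_warning(self):
        with pytest.warns(UserWarning, match="defaulted"):
            tree = parse_newick("(A,B);")
        C, _ = phylo_covariance(tree)
        assert np.allclose(np.diag(C), 1.0)

    def test_round_trip_preserves_topology_and_lengths(self):
        tree = parse_newick(THREE_TAXON)
        again = parse_newick(write_newick(tree))
        l1, d1 = _patristic(tree)
        l2, d2 = _patristic(again)
        order = [l2.index(x) for x in l1]
        np.testing.assert_allclose(d1, d2[np.ix_(order, order)])

    def test_malformed_text_rejected(self):
        with pytest.raises(SpliceRatioError, match="parse error"):
            parse_newick("((A:1,B:1;")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(SpliceRatioError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(SpliceRatioError, match="negative"):
            parse_newick("((A:1,B:-1):1,C:2);")


class TestPrune:
    def test_prune_to_all_tips_is_identity(self):
        tree = parse_newick(THREE_TAXON)
        pruned = prune_to(tree, {"A", "B", "C"})
        l1, d1 = _patristic(tree)
        l2, d2 = _patristic(pruned)
        order = [l2.index(x) for x in l1]
        np.testing.assert_allclose(d1, d2[np.ix_(order, order)])

    def test_path_lengths_preserved_after_collapse(self):
        pruned = prune_to(parse_newick(THREE_TAXON), {"A", "C"})
        C, labels = phylo_covariance(pruned)
        assert sorted(labels) == ["A", "C"]
        np.testing.assert_allclose(np.diag(C), [2.0, 2.0])

    def test_patristic_distances_invariant_on_random_tree(self):
        tree, _, _, labels = simulate_tree_traits(12, 0.0, 1.0, seed=3)
        keep = set(labels[::2])
        l1, d1 = _patristic(tree)
        l2, d2 = _patristic(prune_to(tree, keep))
        idx1 = [l1.index(x) for x in sorted(keep)]
        idx2 = [l2.index(x) for x in sorted(keep)]
        np.testing.assert_allclose(
            d1[np.ix_(idx1, idx1)], d2[np.ix_(idx2, idx2)], atol=1e-9
        )

    def test_empty_intersection_errors(self):
        with pytest.raises(SpliceRatioError, match="missing"):
            prune_to(parse_newick(THREE_TAXON), {"X", "Y"})


class TestCovariance:
    def test_lambda_one_hand_values(self):
        C, labels = phylo_covariance(parse_newick(THREE_TAXON), lam=1.0)
        idx = {lab: i for i, lab in enumerate(labels)}
        a, b, c = idx["A"], idx["B"], idx["C"]
        assert C[a, b] == 1.0
        assert C[a, a] == C[b, b] == C[c, c] == 2.0
        assert C[a, c] == C[b, c] == 0.0

    def test_lambda_zero_is_diagonal(self):
        C, _ = phylo_covariance(parse_newick(THREE_TAXON), lam=0.0)
        np.testing.assert_allclose(C, np.diag([2.0, 2.0, 2.0]))

    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0])
    def test_positive_semidefinite(self, lam):
        tree, _, _, _ = simulate_tree_traits(20, 0.0, 1.0, seed=7)
        C, _ = phylo_covariance(tree, lam=lam)
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-9


class TestPGLS:
    def test_three_taxon_closed_form(self):
        """GLS slope matches the explicit matrix-inverse solution."""
        tree = parse_newick(THREE_TAXON)
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.3, 1.1, 2.4])
        V = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        X = np.column_stack([np.ones(3), x])
        Vi = np.linalg.inv(V)
        expected = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        fit = pgls_fit(x, y, tree, species=["A", "B", "C"], lam=1.0)
        assert fit.beta == pytest.approx(expected[1], abs=1e-10)
        assert fit.intercept == pytest.approx(expected[0], abs=1e-10)

    def test_lambda_zero_equals_ols_on_ultrametric_tree(self):
        from scipy.stats import linregress

        tree, x, y, labels = simulate_tree_traits(32, 0.5, 1.0, seed=5)
        fit = pgls_fit(x, y, tree, species=labels, lam=0.0)
        ols = linregress(x, y)
        assert fit.beta == pytest.approx(ols.slope, abs=1e-8)
        assert fit.p_beta == pytest.approx(ols.pvalue, abs=1e-8)

    def test_matches_statsmodels_gls_at_fixed_lambda(self):
        import statsmodels.api as sm

        tree, x, y, labels = simulate_tree_traits(24, 0.8, 0.6, seed=11)
        C, clabels = phylo_covariance(tree, lam=0.6)
        order = [clabels.index(s) for s in labels]
        V = C[np.ix_(order, order)]
        ref = sm.GLS(y, sm.add_constant(x), sigma=V).fit()
        fit = pgls_fit(x, y, tree, species=labels, lam=0.6)
        assert fit.beta == pytest.approx(ref.params[1], rel=1e-8)
        assert fit.se_beta == pytest.approx(ref.bse[1], rel=1e-8)
        assert fit.p_beta == pytest.approx(ref.pvalues[1], rel=1e-6)

    def test_branch_length_rescaling_invariance(self):
        tree, x, y, labels = simulate_tree_traits(16, 0.4, 1.0, seed=13)
        fit1 = pgls_fit(x, y, tree, species=labels)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 37.5
        fit2 = pgls_fit(x, y, tree, species=labels)
        assert fit2.beta == pytest.approx(fit1.beta, rel=1e-6)
        assert fit2.p_beta == pytest.approx(fit1.p_beta, rel=1e-5)
        assert fit2.lambda_hat == pytest.approx(fit1.lambda_hat, abs=1e-4)

    def test_tip_order_permutation_invariance(self):
        rng = np.random.default_rng(17)
        tree, x, y, labels = simulate_tree_traits(16, 0.4, 1.0, seed=17)
        perm = rng.permutation(len(labels))
        fit1 = pgls_fit(x, y, tree, species=labels)
        fit2 = pgls_fit(
            x[perm], y[perm], tree, species=[labels[i] for i in perm]
        )
        assert fit2.beta == pytest.approx(fit1.beta, rel=1e-10)
        assert fit2.lambda_hat == pytest.approx(fit1.lambda_hat, abs=1e-6)

    def test_parameter_recovery_single_run(self):
        tree, x, y, labels = simulate_tree_traits(64, 0.5, 1.0, sigma=1.0, seed=23)
        fit = pgls_fit(x, y, tree, species=labels)
        assert abs(fit.beta - 0.5) < 2 * fit.se_beta
        assert fit.lambda_hat > 0.5

    def test_constant_predictor_rejected(self):
        tree, _, y, labels = simulate_tree_traits(8, 0.0, 1.0, seed=29)
        with pytest.raises(SpliceRatioError, match="constant"):
            pgls_fit(np.ones(8), y, tree, species=labels)

    def test_unknown_species_rejected(self):
        tree, x, y, labels = simulate_tree_traits(8, 0.0, 1.0, seed=31)
        with pytest.raises(SpliceRatioError, match="not in tree"):
            pgls_fit(x, y, tree, species=["nope"] * 8)


class TestEstimatorWrapper:
    def test_fit_predict_and_params(self):
        tree, x, y, labels = simulate_tree_traits(24, 0.7, 1.0, seed=37)
        est = PGLS(tree=tree, species=labels)
        assert est.get_params()["lam"] == "ml"
        est.fit(x[:, None], y)
        assert est.coef_.shape == (1,)
        assert 0.0 <= est.lambda_ <= 1.0
        pred = est.predict(np.array([[0.0], [1.0]]))
        assert pred[1] - pred[0] == pytest.approx(est.coef_[0])

    def test_accepts_newick_text(self):
        est = PGLS(tree=THREE_TAXON, species=["A", "B", "C"], lam=1.0)
        est.fit(np.array([0.0, 1.0, 2.0]), np.array([0.1, 1.2, 1.9]))
        assert est.n_species_ == 3
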