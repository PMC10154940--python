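"""Newick handling, Brownian covariance, and PGLS with Pagel's lambda."""

import numpy as np
import pandas as pd
import pytest

from ornametrics import (
    PGLS,
    brownian_vcv,
    make_tree,
    pagel_transform,
    pgls_fit,
    read_newick,
    simulate_brownian,
)


def mrca_depth_oracle(tree):
    """Brute-force per-pair root-to-MRCA path lengths via dendropy MRCA."""
    t = tree.tree
    t.calc_node_root_distances(return_leaf_distances_only=False)
    labels = tree.tip_labels
    n = len(labels)
    V = np.zeros((n, n))
    pdm_taxa = {leaf.taxon.label: leaf.taxon for leaf in t.leaf_node_iter()}
    for i in range(n):
        for j in range(n):
            mrca = t.mrca(taxa=[pdm_taxa[labels[i]], pdm_taxa[labels[j]]])
            V[i, j] = mrca.root_distance if i != j else \
                [l for l in t.leaf_node_iter()
                 if l.taxon.label == labels[i]][0].root_distance
    return pd.DataFrame(V, index=labels, columns=labels)


class TestNewick:
    def test_three_taxon_parse(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        assert sorted(tree.tip_labels) == ["A", "B", "C"]
        assert tree.tip_depths().round(9).tolist() == [2.0, 2.0, 2.0]

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError):
            read_newick("(A:1,B:1")

    def test_seventeen_tip_round_trip_preserves_paths(self):
        tree = make_tree(17, seed=9)
        back = read_newick(tree.to_newick())
        V1 = brownian_vcv(tree)
        V2 = brownian_vcv(back).loc[V1.index, V1.columns]
        np.testing.assert_allclose(V2.values, V1.values, atol=1e-12)

    def test_pruning_drops_missing_species_with_warning(self):
        tree = read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        with pytest.warns(UserWarning, match="dropped.*Zz"):
            pruned = tree.pruned_to(["A", "B", "C", "Zz"])
        assert sorted(pruned.tip_labels) == ["A", "B", "C"]


class TestBrownianVCV:
    def test_two_taxon_cherry(self):
        V = brownian_vcv(read_newick("(A:1,B:1);"))
        np.testing.assert_allclose(V.values, np.eye(2))

    def test_three_taxon_path_arithmetic(self):
        V = brownian_vcv(read_newick("((A:1,B:1):1,C:2);"))
        assert V.loc["A", "A"] == pytest.approx(2.0)
        assert V.loc["A", "B"] == pytest.approx(1.0)
        assert V.loc["A", "C"] == pytest.approx(0.0)
        assert V.loc["C", "C"] == pytest.approx(2.0)

    def test_matches_mrca_oracle_on_random_tree(self):
        tree = make_tree(20, seed=31)
        V = brownian_vcv(tree)
        O = mrca_depth_oracle(tree)
        np.testing.assert_allclose(V.values, O.values, atol=1e-12)

    def test_positive_semidefinite(self):
        V = brownian_vcv(make_tree(25, seed=4)).values
        eig = np.linalg.eigvalsh(V)
        assert eig.min() >= -1e-10


class TestPagelTransform:
    def test_endpoints_and_midpoint(self):
        V = brownian_vcv(read_newick("((A:1,B:1):1,C:2);"))
        np.testing.assert_allclose(pagel_transform(V, 1.0).values, V.values)
        V0 = pagel_transform(V, 0.0)
        np.testing.assert_allclose(V0.values, np.diag(np.diag(V.values)))
        assert pagel_transform(V, 0.5).loc["A", "B"] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        V = brownian_vcv(read_newick("(A:1,B:1);"))
        with pytest.raises(ValueError):
            pagel_transform(V, 1.2)


def star_tree(n=20):
    return read_newick("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")


class TestPGLS:
    @pytest.fixture
    def star_data(self):
        rng = np.random.default_rng(7)
        idx = [f"s{i}" for i in range(20)]
        x = pd.Series(rng.normal(size=20), index=idx, name="x")
        y = pd.Series(1.0 + 0.5 * x.values + rng.normal(0, 0.4, 20),
                      index=idx, name="y")
        return x, y

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_star_tree_equals_ols_any_lambda(self, star_data, lam):
        import statsmodels.api as sm

        x, y = star_data
        res = pgls_fit(y, x.to_frame(), star_tree(), lam=lam)
        ols = sm.OLS(y.values, sm.add_constant(x.values)).fit()
        np.testing.assert_allclose(res.params.values, ols.params, atol=1e-8)
        np.testing.assert_allclose(res.bse.values, ols.bse, atol=1e-8)
        np.testing.assert_allclose(res.pvalues.values, ols.pvalues, atol=1e-8)

    def test_lambda_zero_on_ultrametric_tree_equals_ols(self):
        import statsmodels.api as sm

        tree = make_tree(24, seed=11)
        rng = np.random.default_rng(3)
        x = pd.Series(rng.normal(size=24), index=tree.tip_labels, name="x")
        y = simulate_brownian(tree, 0.5, x, 1.0, lam=1.0, seed=5)
        res = pgls_fit(y, x.to_frame(), tree, lam=0.0)
        ols = sm.OLS(y.values, sm.add_constant(x.values)).fit()
        np.testing.assert_allclose(res.params.values, ols.params, atol=1e-8)

    def test_branch_length_rescaling_leaves_beta_unchanged(self):
        tree = make_tree(15, seed=2)
        rng = np.random.default_rng(9)
        x = pd.Series(rng.normal(size=15), index=tree.tip_labels, name="x")
        y = simulate_brownian(tree, 0.7, x, 1.0, lam=1.0, seed=6)
        r1 = pgls_fit(y, x.to_frame(), tree, lam=1.0)
        r2 = pgls_fit(y, x.to_frame(), tree.scale_depth_to(37.0), lam=1.0)
        np.testing.assert_allclose(r2.params.values, r1.params.values,
                                   atol=1e-8)

    def test_singular_design_rejected(self, star_data):
        x, y = star_data
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="singular"):
            PGLS(y, X, star_tree())

    def test_disjoint_species_rejected(self, star_data):
        x, y = star_data
        other = read_newick("(p:1,q:1,r:1,t:1,u:1,v:1);")
        with pytest.raises(ValueError):
            PGLS(y, x.to_frame(), other)

    def test_anova_sequential_ss_adds_to_total(self):
        tree = make_tree(20, seed=13)
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x1": rng.normal(size=20),
                          "x2": rng.normal(size=20)},
                         index=tree.tip_labels)
        y = simulate_brownian(tree, 0.5, X["x1"], 1.0, 1.0, seed=8)
        res = PGLS(y, X, tree).fit(1.0)
        an = res.anova()
        # total generalized SS about the intercept-only GLS fit
        yw, Xw = res.model.whiten(1.0)
        b0, *_ = np.linalg.lstsq(Xw[:, :1], yw, rcond=None)
        total = float(((yw - Xw[:, :1] @ b0) ** 2).sum())
        assert an["ss"].sum() == pytest.approx(total, rel=1e-9)

    def test_summary_mentions_lambda_and_terms(self, star_data):
        x, y = star_data
        res = pgls_fit(y, x.to_frame(), star_tree(), lam=0.0)
        text = res.summary()
        assert "lambda" in text and "x" in text and "PGLS" in text


class TestLambdaEstimation:
    def test_profile_on_two_point_grid(self):
        tree = make_tree(20, seed=17)
        x = pd.Series(np.zeros(20), index=tree.tip_labels, name="x")
        y = simulate_brownian(tree, 0.0, x, 1.0, lam=1.0, seed=3)
        prof = PGLS(y, pd.DataFrame(index=tree.tip_labels),
                    tree).lambda_profile([0.0, 1.0])
        assert len(prof) == 2
        assert prof.attrs["lam_hat"] in (0.0, 1.0)
        assert prof.attrs["lam_hat"] == \
            prof.loc[prof["loglik"].idxmax(), "lam"]

    @pytest.mark.parametrize("lam_true,check", [
        (0.0, lambda hats: np.mean(hats <= 0.2) >= 0.9),
        (1.0, lambda hats: np.mean(hats >= 0.8) >= 0.9),
    ])
    def test_ml_lambda_calibrated(self, lam_true, check):
        tree = make_tree(100, seed=5)
        zeros = np.zeros(100)
        hats = []
        for i in range(20):
            x = simulate_brownian(tree, 0.0, zeros, 1.0, 1.0, seed=3000 + i)
            x.name = "x"
            y = simulate_brownian(tree, 0.5, x, 1.0, lam_true, seed=4000 + i)
            hats.append(PGLS(y, x.to_frame(), tree).fit("ML").lam)
        assert check(np.asarray(hats))
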