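import numpy as np
import pandas as pd
import pytest
from statsmodels.multivariate.manova import MANOVA

from pollenmorph import (PhyloTree, pca_fit, shape_at, manova_groups,
                         phylomorphospace, efa_forward, ou_covariance)
from pollenmorph.simulate import SimulationSpec, sim_outlines, sim_tree


class TestPCA:
    def test_collinear_rows_load_on_one_component(self):
        m = pca_fit(np.array([[0, 0], [1, 2], [2, 4]], float))
        assert m.variance_fractions[0] == pytest.approx(1.0)

    def test_unit_square_splits_variance_evenly(self):
        m = pca_fit(np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float))
        assert np.allclose(m.variance_fractions, [0.5, 0.5])

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pca_fit(np.ones((5, 3)))

    def test_loadings_orthonormal_and_scores_centered(self):
        rng = np.random.default_rng(0)
        m = pca_fit(rng.normal(size=(40, 6)))
        assert np.abs(m.loadings @ m.loadings.T - np.eye(6)).max() < 1e-8
        assert np.abs(m.scores.mean(axis=0)).max() < 1e-8
        assert np.all(np.diff(m.variance_fractions) <= 1e-12)
        assert m.variance_fractions.sum() == pytest.approx(1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        m = pca_fit(X)
        back = m.scores @ m.loadings + m.mean_vector
        assert np.abs(back - X).max() < 1e-8

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 4))
        m1, m2 = pca_fit(X), pca_fit(X.copy())
        assert np.allclose(m1.scores, m2.scores)
        for row in m1.loadings:
            assert row[np.argmax(np.abs(row))] > 0


@pytest.fixture(scope="module")
def model():
    outs = (sim_outlines(SimulationSpec(seed=3), "prolate_pseudocolpate", 30)
            + sim_outlines(SimulationSpec(seed=3), "oblate_triangular", 30))
    M = np.vstack([efa_forward(o, 8).flatten() for o in outs])
    return pca_fit(M)


class TestShapeAt:
    def test_zero_score_is_mean_shape(self, model):
        o = shape_at(model, 0, 0.0)
        mean_coeffs = model.mean_vector.reshape(-1, 4)
        from pollenmorph.efa import reconstruct_xy, HarmonicCoefficientSet
        x, y = reconstruct_xy(HarmonicCoefficientSet(0, 0, mean_coeffs), 256)
        assert np.allclose(o.points, np.column_stack([x, y]))

    def test_projected_scores_round_trip(self, model):
        sd = np.sqrt(model.eigenvalues[0])
        for score in (2 * sd, -2 * sd):
            # the analytic coefficient vector projects back exactly ...
            vec = model.mean_vector + score * model.loadings[0]
            proj = (vec - model.mean_vector) @ model.loadings[0]
            assert proj == pytest.approx(score, abs=1e-6)
            # ... and re-measuring the drawn outline (without renormalizing,
            # which would rescale by its own first ellipse) agrees up to
            # polygon discretization error
            o = shape_at(model, 0, score, n_points=1024)
            cs = efa_forward(o, 8, normalize=False)
            remeasured = (cs.flatten() - model.mean_vector) @ model.loadings[0]
            assert remeasured == pytest.approx(score, rel=5e-2)

    def test_component_out_of_range(self, model):
        with pytest.raises(IndexError):
            shape_at(model, model.n_components + 3, 0.0)


class TestMANOVA:
    def test_matches_statsmodels_pillai(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 4))
        X[30:] += [1, 0, 0.5, 0]
        labels = ["a"] * 30 + ["b"] * 30
        res = manova_groups(X, labels, m=4, n_perm=99)
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(4)])
        df["g"] = labels
        ref = MANOVA.from_formula("v0+v1+v2+v3 ~ g", data=df).mv_test()
        tbl = ref.results["g"]["stat"].loc["Pillai's trace"]
        assert res.statistic == pytest.approx(float(tbl["Value"]), abs=1e-10)
        assert res.f_approx == pytest.approx(float(tbl["F Value"]), rel=1e-8)
        assert res.p == pytest.approx(float(tbl["Pr > F"]), abs=1e-10)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(5, 1, (50, 3))])
        res = manova_groups(X, ["a"] * 50 + ["b"] * 50, m=3, n_perm=999)
        assert res.p < 0.001
        assert res.p_permutation < 0.01

    def test_null_rarely_rejects(self):
        rng = np.random.default_rng(10)
        hits = 0
        for s in range(50):
            X = rng.normal(size=(100, 5))
            res = manova_groups(X, ["a"] * 50 + ["b"] * 50, m=5, n_perm=1)
            hits += res.p > 0.05
        assert hits >= 45  # >= 90% of null datasets non-significant

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            manova_groups(np.zeros((3, 2)), ["a", "a", "b"], m=2)


class TestPhylomorphospace:
    def test_two_tip_symmetry(self):
        tr = PhyloTree.from_newick("(A:1,B:1);")
        df, edges = phylomorphospace(
            tr, pd.DataFrame([[0, 0], [2, 2]], index=["A", "B"]))
        root = df[~df.is_tip].iloc[0]
        assert root.iloc[0] == pytest.approx(1.0)
        assert len(edges) == tr.n_edges

    def test_star_tree_root_is_mean(self, star4):
        Y = pd.DataFrame(np.arange(8.0).reshape(4, 2), index=list("ABCD"))
        df, _ = phylomorphospace(star4, Y)
        root = df[~df.is_tip].iloc[0, :2].to_numpy()
        assert np.allclose(root, Y.to_numpy().mean(axis=0))

    def test_matches_dense_gls_oracle(self):
        tr = PhyloTree.from_newick("((A:1,B:2.5):1.5,(C:0.5,D:3):1);")
        y = pd.DataFrame({"x": [1.0, -0.5, 2.0, 0.3]}, index=list("ABCD"))
        df, _ = phylomorphospace(tr, y)
        V = ou_covariance(tr, 0.0)
        iV = np.linalg.inv(V)
        one = np.ones(4)
        yv = np.array([y.loc[l, "x"] for l in tr.tip_labels])
        mu = (one @ iV @ yv) / (one @ iV @ one)
        D = tr.descent_matrix()
        expected = []
        for v in range(tr.n_tips, tr.n_nodes):
            cov = np.array([tr.depth[v] if D[i, v]
                            else tr.depth[tr.mrca([i, tr.clade_tips(v)[0]])]
                            for i in range(4)])
            expected.append(mu + cov @ iV @ (yv - mu))
        got = df[~df.is_tip].x.to_numpy()
        assert np.abs(got - np.array(expected)).max() < 1e-8

    def test_shift_equivariance_and_tip_order_invariance(self, balanced4):
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(rng.normal(size=(4, 2)), index=list("ABCD"))
        df1, _ = phylomorphospace(balanced4, Y)
        df2, _ = phylomorphospace(balanced4, Y + 10.0)
        assert np.abs((df2.iloc[:, :2] - df1.iloc[:, :2]) - 10.0).to_numpy().max() < 1e-10
        df3, _ = phylomorphospace(balanced4, Y.loc[list("DCBA")])
        assert np.allclose(df1.iloc[:, :2], df3.iloc[:, :2])

    def test_missing_tip_listed(self, balanced4):
        with pytest.raises(ValueError, match="D"):
            phylomorphospace(balanced4,
                             pd.DataFrame(np.zeros((3, 2)), index=list("ABC")))
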