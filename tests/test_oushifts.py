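import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pollenmorph import (PhyloTree, ou_covariance, detect_shifts,
                         bootstrap_support, collapse_convergent,
                         regime_painting)
from pollenmorph.oushifts import (CandidateFit, ou_loglik, score_criterion,
                                  ShiftWorkspace)
from pollenmorph.simulate import SimulationSpec, sim_tree, sim_ou_traits


class TestLoglik:
    def test_iid_reduction_on_star_tree(self):
        star = PhyloTree.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        rng = np.random.default_rng(0)
        y = rng.normal(size=5)
        X = np.ones((5, 1))
        ll = ou_loglik(y, X, np.array([0.3]), 0.0, 1.7, star)
        ref = stats.norm(0.3, np.sqrt(1.7)).logpdf(y).sum()
        assert ll == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tr = sim_tree(SimulationSpec(seed=seed, n_tips=int(rng.integers(4, 11)),
                                     depth=8.0))
        n = tr.n_tips
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = rng.normal(size=2)
        alpha = float(rng.uniform(0, 1.5))
        s2 = float(rng.uniform(0.3, 2.0))
        ll = ou_loglik(y, X, beta, alpha, s2, tr, method="tree")
        oracle = stats.multivariate_normal(
            mean=X @ beta, cov=s2 * ou_covariance(tr, alpha)).logpdf(y)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_residual_scaling_quadratic(self):
        tr = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        y = np.array([1.0, -1.0, 2.0, 0.5])
        X = np.zeros((4, 1))
        b = np.array([0.0])
        ll1 = ou_loglik(y, X, b, 0.3, 1.0, tr)
        ll2 = ou_loglik(2 * y, X, b, 0.3, 1.0, tr)
        base = ou_loglik(0 * y, X, b, 0.3, 1.0, tr)
        assert (ll2 - base) == pytest.approx(4 * (ll1 - base), rel=1e-10)


class TestCriterion:
    def _fit(self, tree64, cols, traits, ws):
        from pollenmorph.oushifts import _refit
        Ys = traits / traits.std(axis=0, ddof=1)
        return _refit(ws, 0.05, cols, Ys)

    def test_bic_of_empty_configuration_exact(self, tree64, workspace64):
        traits = sim_ou_traits(tree64, SimulationSpec(seed=1)).to_numpy()
        fit = self._fit(tree64, (), traits, workspace64)
        bic = score_criterion(fit, "BIC")
        n, q = tree64.n_tips, 1
        assert bic == pytest.approx(-2 * fit.loglik + 3 * q * np.log(n))

    def test_spurious_shift_raises_pbic_on_null(self, tree64, workspace64):
        rng = np.random.default_rng(0)
        worse = 0
        n_rep = 20
        for s in range(n_rep):
            traits = sim_ou_traits(tree64, SimulationSpec(seed=40 + s)).to_numpy()
            empty = score_criterion(self._fit(tree64, (), traits, workspace64))
            j = int(rng.integers(len(workspace64.candidate_edges)))
            spur = score_criterion(self._fit(tree64, (j,), traits, workspace64))
            worse += spur > empty
        assert worse >= 0.9 * n_rep


class TestDetect:
    def test_null_rarely_detects(self, tree64, workspace64):
        detected = [detect_shifts(sim_ou_traits(tree64, SimulationSpec(seed=500 + s)),
                                  tree64, workspace=workspace64).n_shifts
                    for s in range(10)]
        assert np.mean(detected) <= 0.2

    def test_planted_shift_recovered(self, tree64, workspace64):
        from pollenmorph.simulate import choose_planted_edge
        edge = choose_planted_edge(tree64, 0.05, 0.1)
        hits = 0
        for s in range(10):
            sp = SimulationSpec(seed=300 + s, shifts=[(edge, 4.0)])
            fit = detect_shifts(sim_ou_traits(tree64, sp), tree64,
                                workspace=workspace64)
            hits += edge in fit.shift_edges
        assert hits >= 8

    def test_tip_order_invariance(self, tree64, workspace64):
        traits = sim_ou_traits(tree64, SimulationSpec(seed=301, shifts=[(68, 4.0)]))
        fit1 = detect_shifts(traits, tree64, workspace=workspace64)
        shuffled = traits.sample(frac=1.0, random_state=0)
        fit2 = detect_shifts(shuffled, tree64, workspace=workspace64)
        assert fit1.shift_edges == fit2.shift_edges

    def test_unmatched_tips_listed(self, tree64):
        traits = pd.DataFrame({"t": np.zeros(3)}, index=["sp001", "sp002", "nope"])
        with pytest.raises(KeyError, match="sp003"):
            detect_shifts(traits, tree64)

    def test_regime_painting_changes_exactly_at_shifts(self, tree64):
        shifts = (68, 99)
        regimes = regime_painting(tree64, shifts)
        for v in range(tree64.n_nodes):
            if v == tree64.root:
                continue
            p = tree64.parent[v]
            if v in shifts:
                assert regimes[v] != regimes[p]
            else:
                assert regimes[v] == regimes[p]


class TestBootstrap:
    def test_no_shifts_gives_empty_map(self, tree64, workspace64):
        traits = sim_ou_traits(tree64, SimulationSpec(seed=502))
        fit = detect_shifts(traits, tree64, workspace=workspace64)
        assert fit.n_shifts == 0
        assert bootstrap_support(fit, traits, tree64, n_boot=3,
                                 workspace=workspace64) == {}

    def test_supports_bounded_and_reproducible(self, tree64, workspace64):
        sp = SimulationSpec(seed=303, shifts=[(106, 5.0)])
        traits = sim_ou_traits(tree64, sp)
        fit = detect_shifts(traits, tree64, workspace=workspace64)
        s1 = bootstrap_support(fit, traits, tree64, n_boot=8, seed=4,
                               workspace=workspace64)
        s2 = bootstrap_support(fit, traits, tree64, n_boot=8, seed=4,
                               workspace=workspace64)
        assert s1 == s2
        assert all(0 <= v <= 1 for v in s1.values())

    def test_invalid_n_boot(self, tree64, workspace64):
        traits = sim_ou_traits(tree64, SimulationSpec(seed=504, shifts=[(106, 5.0)]))
        fit = detect_shifts(traits, tree64, workspace=workspace64)
        with pytest.raises(ValueError):
            bootstrap_support(fit, traits, tree64, n_boot=0, workspace=workspace64)


class TestCollapse:
    def test_no_shifts_returns_single_regime_unchanged(self, tree64, workspace64):
        traits = sim_ou_traits(tree64, SimulationSpec(seed=505))
        fit = detect_shifts(traits, tree64, workspace=workspace64)
        out = collapse_convergent(fit, traits, tree64)
        assert out.regimes.max() == 0

    def test_equal_optima_merge_distant_do_not(self, tree64, workspace64):
        merged_equal = merged_far = runs_equal = runs_far = 0
        for s in range(3):
            for far, delta2 in ((False, 4.0), (True, 14.0)):
                sp = SimulationSpec(seed=700 + s,
                                    shifts=[(106, 4.0), (75, delta2)])
                traits = sim_ou_traits(tree64, sp)
                fit = detect_shifts(traits, tree64, workspace=workspace64)
                if not {106, 75} <= set(fit.shift_edges):
                    continue
                col = collapse_convergent(fit, traits, tree64)
                same = col.regimes[106] == col.regimes[75]
                if far:
                    runs_far += 1
                    merged_far += same
                else:
                    runs_equal += 1
                    merged_equal += same
        assert runs_equal > 0 and runs_far > 0
        assert merged_equal > runs_equal / 2
        assert merged_far <= runs_far / 2
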