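"""The phylogenetic mixed model: Gibbs sampler, GLS oracle, diagnostics."""

import numpy as np
import pytest

from wingcontrast.pcmm import (
    MCMCSchedule,
    PriorSpec,
    bayes_r2,
    effective_sample_size,
    fit_gls,
    fit_mcmc,
    fit_tree_set,
    hpd_interval,
    pmcmc,
    validation_regression,
)
from wingcontrast.phylo import simulate_yule, vcv_from_tree
from wingcontrast.synth import simulate_response

SHORT = MCMCSchedule(n_iter=4000, burn_in=800, thin=4, seed=11)


class TestPmcmc:
    def test_all_positive_reports_two_over_n(self):
        assert pmcmc(np.ones(100)) == pytest.approx(0.02)

    def test_symmetric_chain_reports_one(self):
        s = np.concatenate([np.ones(50), -np.ones(50)])
        assert pmcmc(s) == 1.0

    def test_seventy_thirty_split(self):
        s = np.concatenate([np.ones(70), -np.ones(30)])
        assert pmcmc(s) == pytest.approx(0.6)

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            pmcmc([1.0])


class TestESS:
    def test_independent_draws(self, rng):
        s = rng.standard_normal(2000)
        assert effective_sample_size(s) == pytest.approx(2000, rel=0.15)

    def test_ar1_closed_form(self, rng):
        rho, n = 0.5, 5000
        s = np.empty(n)
        s[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            s[i] = rho * s[i - 1] + eps[i]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(s) == pytest.approx(expected, rel=0.2)

    def test_constant_chain_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert effective_sample_size(np.full(100, 3.0)) == 0.0

    def test_agrees_with_arviz(self, rng):
        az = pytest.importorskip("arviz")
        rho, n = 0.7, 4000
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        s = np.empty(n)
        s[0] = rng.standard_normal()
        for i in range(1, n):
            s[i] = rho * s[i - 1] + eps[i]
        ours = effective_sample_size(s)
        theirs = float(az.ess(s[None, :]))
        assert ours == pytest.approx(theirs, rel=0.25)


class TestHPD:
    def test_hpd_shorter_than_quantile_for_skewed(self, rng):
        s = rng.gamma(2.0, size=20000)
        lo_h, hi_h = hpd_interval(s)
        lo_q, hi_q = hpd_interval(s, method="quantile")
        assert (hi_h - lo_h) <= (hi_q - lo_q)
        assert lo_h < np.median(s) < hi_h

    def test_quantile_interval_matches_numpy(self, rng):
        s = rng.standard_normal(5000)
        lo, hi = hpd_interval(s, method="quantile")
        assert lo == pytest.approx(np.quantile(s, 0.025))
        assert hi == pytest.approx(np.quantile(s, 0.975))


class TestSchedule:
    def test_retained_draw_count_floor(self):
        assert MCMCSchedule().n_retained == (75_000 - 7_500) // 40 == 1687

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            MCMCSchedule(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCSchedule(thin=0)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(resid_nu=-1)


class TestGLS:
    def test_identity_covariance_equals_ols(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        fit = fit_gls(y, X, np.eye(n))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit["beta"], ols, atol=1e-10)

    def test_noiseless_recovery_any_lambda(self, vcv50, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        beta = np.array([2.0, -1.5])
        fit = fit_gls(X @ beta, X, vcv50)
        assert np.allclose(fit["beta"], beta, atol=1e-8)

    def test_lambda_recovery_simulation(self):
        # median over repeated seeds within +-0.1 of the simulation truth
        lams = []
        for s in range(5):
            tree = simulate_yule(400, 1.0, seed=60 + s)
            V = vcv_from_tree(tree, scale=True)
            X = np.ones((400, 1))
            y = simulate_response(X, V.matrix, [5.0], 0.6, 4.0, 70 + s)
            lams.append(fit_gls(y, X, V)["lambda"])
        assert abs(np.median(lams) - 0.6) < 0.1

    def test_nonultrametric_covariance_rejected(self):
        from wingcontrast.phylo import read_newick, vcv_from_tree as vcv

        V = vcv(read_newick("((A:1,B:1):1,C:5);"), scale=False)  # uneven tip depths
        with pytest.raises(ValueError, match="scaled"):
            fit_gls(np.zeros(3), np.ones((3, 1)), V)


class TestMCMC:
    def test_deterministic_under_seed(self, vcv50, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = simulate_response(X, vcv50.matrix, [1.0, 0.5], 0.5, 1.0, 3)
        a = fit_mcmc(y, X, vcv50, schedule=SHORT)
        b = fit_mcmc(y, X, vcv50, schedule=SHORT)
        assert np.array_equal(a.draws["beta"], b.draws["beta"])
        c = fit_mcmc(y, X, vcv50, schedule=MCMCSchedule(4000, 800, 4, seed=12))
        assert not np.array_equal(a.draws["beta"], c.draws["beta"])

    def test_oracle_equivalence_data_dominated(self):
        tree = simulate_yule(300, 1.0, seed=21)
        V = vcv_from_tree(tree, scale=True)
        rng = np.random.default_rng(22)
        X = np.column_stack([np.ones(300), rng.standard_normal((300, 2))])
        y = simulate_response(X, V.matrix, [1.0, 2.0, -1.0], 0.5, 1.0, 23)
        mc = fit_mcmc(y, X, V, schedule=SHORT)
        gls = fit_gls(y, X, V)
        mcse = mc.sd / np.sqrt(np.maximum(mc.ess, 1.0))
        comb = np.sqrt(mcse**2 + gls["se"] ** 2)
        assert (np.abs(mc.mean - gls["beta"]) < 2 * comb).all()

    @pytest.mark.parametrize("lam_true,check", [(0.0, lambda l: l < 0.15), (1.0, lambda l: l > 0.85)])
    def test_lambda_extremes(self, lam_true, check):
        tree = simulate_yule(300, 1.0, seed=31)
        V = vcv_from_tree(tree, scale=True)
        X = np.ones((300, 1))
        y = simulate_response(X, V.matrix, [0.0], lam_true, 4.0, 32)
        fit = fit_mcmc(y, X, V, schedule=SHORT)
        assert check(fit.lambda_mean)

    def test_retained_draws_and_summary_shapes(self, vcv50):
        y = np.arange(50, dtype=float)
        fit = fit_mcmc(y, np.ones((50, 1)), vcv50, schedule=SHORT, names=["intercept"])
        assert fit.n_draws == SHORT.n_retained == len(fit.draws["beta"])
        assert fit.names == ["intercept"]
        assert (fit.ci_lower <= fit.ci_upper).all()
        assert 0.0 <= fit.lambda_mean <= 1.0
        assert ((fit.pmcmc > 0) & (fit.pmcmc <= 1)).all()

    def test_permutation_invariance_to_mc_error(self, vcv50, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = simulate_response(X, vcv50.matrix, [1.0, 1.0], 0.5, 1.0, 41)
        base = fit_mcmc(y, X, vcv50, schedule=SHORT)
        perm = rng.permutation(50)
        Vp = vcv50.matrix[np.ix_(perm, perm)]
        permuted = fit_mcmc(y[perm], X[perm], Vp, schedule=SHORT)
        mcse = np.sqrt(
            base.sd**2 / np.maximum(base.ess, 1) + permuted.sd**2 / np.maximum(permuted.ess, 1)
        )
        assert (np.abs(base.mean - permuted.mean) < 5 * mcse).all()

    def test_dimension_mismatch_rejected(self, vcv50):
        with pytest.raises(ValueError):
            fit_mcmc(np.zeros(10), np.ones((10, 1)), vcv50)


class TestTreeSet:
    def _data(self, n=40, seed=51):
        tree = simulate_yule(n, 1.0, seed=seed)
        V = vcv_from_tree(tree, scale=True)
        rng = np.random.default_rng(seed + 1)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = simulate_response(X, V.matrix, [1.0, 0.5], 0.5, 1.0, seed + 2)
        return tree, V, X, y

    def test_identical_trees_match_single_fit(self):
        tree, V, X, y = self._data()
        avg = fit_tree_set(y, X, [tree, tree, tree], k=3, schedule=SHORT, seed=5)
        single = fit_mcmc(y, X, V, schedule=SHORT)
        mcse = single.sd / np.sqrt(np.maximum(single.ess, 1))
        assert (np.abs(avg.mean - single.mean) < 5 * mcse).all()

    def test_deterministic_and_arithmetic_averaging(self):
        tree, V, X, y = self._data()
        trees = [tree, simulate_yule(40, 1.0, seed=52), simulate_yule(40, 1.0, seed=53)]
        a = fit_tree_set(y, X, trees, k=2, schedule=SHORT, seed=8, species_ids=tree.tip_labels)
        b = fit_tree_set(y, X, trees, k=2, schedule=SHORT, seed=8, species_ids=tree.tip_labels)
        assert np.array_equal(a.mean, b.mean)
        # averaged fields equal hand-computed means of the per-tree summaries
        assert np.allclose(a.mean, np.mean([f.mean for f in a.per_tree], axis=0))
        assert np.allclose(a.pmcmc, np.mean([f.pmcmc for f in a.per_tree], axis=0))
        assert a.lambda_mean == pytest.approx(np.mean([f.lambda_mean for f in a.per_tree]))
        assert a.n_trees == 2

    def test_k_larger_than_tree_set_rejected(self):
        tree, V, X, y = self._data()
        with pytest.raises(ValueError):
            fit_tree_set(y, X, [tree], k=2, schedule=SHORT)

    def test_failure_names_tree_index(self):
        tree, V, X, y = self._data()
        bad = simulate_yule(12, 1.0, seed=54)  # wrong tip count
        with pytest.raises(RuntimeError, match="tree index"):
            fit_tree_set(y, X, [bad], k=1, schedule=SHORT)


class TestValidationRegression:
    def test_noiseless_linear_relation(self, vcv50, rng):
        x = rng.standard_normal(50)
        y = 3.0 + 2.0 * x
        fit = validation_regression(y, x, vcv50, schedule=SHORT)
        assert fit.mean[1] == pytest.approx(2.0 * x.std(ddof=1), abs=0.05)
        assert fit.draws["r2_mean"] > 0.99

    def test_independent_pairs_null(self, vcv50, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        fit = validation_regression(y, x, vcv50, schedule=SHORT)
        assert fit.ci_lower[1] < 0 < fit.ci_upper[1]
        assert fit.draws["r2_mean"] < 0.3

    def test_constant_predictor_rejected(self, vcv50):
        with pytest.raises(ValueError):
            validation_regression(np.zeros(50), np.ones(50), vcv50)


def test_bayes_r2_perfect_fit_limits(rng):
    X = np.column_stack([np.ones(30), rng.standard_normal(30)])
    beta_draws = np.tile([0.0, 1.0], (10, 1))
    r2 = bayes_r2(beta_draws, X, np.zeros(10), np.full(10, 1e-12))
    assert np.allclose(r2, 1.0, atol=1e-6)
    r2_null = bayes_r2(np.zeros((10, 2)) + [5.0, 0.0], X, np.ones(10), np.ones(10))
    assert np.allclose(r2_null, 0.0)
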