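"""FIML engine: deviance identities, optimization, profile CIs and LRT."""

import numpy as np
import pytest
from scipy import stats

import twinwaves as tw
from twinwaves import sem
from twinwaves.twin import _ace_model, family_table

_LOG2PI = np.log(2 * np.pi)


def _gaussian_deviance(X):
    """Closed-form -2lnL of the saturated Gaussian model at the ML moments."""
    n, k = X.shape
    S = np.cov(X.T, ddof=0) if k > 1 else np.array([[X.var(ddof=0)]])
    return n * (k * _LOG2PI + np.linalg.slogdet(S)[1] + k)


def _fixed_normal_model(k):
    """Free means, fixed identity-scaled covariance (for exact CI checks)."""
    def implied(p):
        return {"all": (p.copy(), np.eye(k))}
    return sem.StructuredModel([f"mu{i}" for i in range(k)], np.zeros(k),
                               [(None, None)] * k, implied)


class TestDeviance:
    def test_saturated_complete_data_equals_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 3)) @ np.diag([1.0, 0.5, 2.0])
        model = sem.saturated_model(3)
        fit = sem.fit_ml(model, {"all": X}, seed=0)
        assert fit.converged
        assert fit.deviance == pytest.approx(_gaussian_deviance(X), abs=1e-4)

    def test_complete_data_fiml_equals_sufficient_statistic_form(self):
        # FIML summed per row == moment-based Gaussian deviance at any params
        rng = np.random.default_rng(1)
        X = rng.standard_normal((150, 2))
        model = sem.saturated_model(2)
        p = np.array([0.3, -0.2, 1.2, 0.4, 0.9])
        mu, sigma = model.implied(p)["all"]
        n, k = X.shape
        S = (X - X.mean(0)).T @ (X - X.mean(0)) / n
        d = X.mean(0) - mu
        siginv = np.linalg.inv(sigma)
        expected = n * (k * _LOG2PI + np.linalg.slogdet(sigma)[1]
                        + np.trace(siginv @ S) + d @ siginv @ d)
        assert sem.fiml_deviance(model, p, {"all": X}) == pytest.approx(
            expected, rel=1e-12)

    def test_all_missing_rows_contribute_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 2))
        X2 = np.vstack([X, np.full((10, 2), np.nan)])
        model = sem.saturated_model(2)
        p = model.start
        assert sem.fiml_deviance(model, p, {"all": X}) == pytest.approx(
            sem.fiml_deviance(model, p, {"all": X2}), rel=1e-12)

    def test_deviance_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 3))
        X[rng.random((100, 3)) < 0.3] = np.nan
        X = X[~np.isnan(X).all(axis=1)]
        model = sem.saturated_model(3)
        p = model.start
        shuffled = X[rng.permutation(len(X))]
        assert sem.fiml_deviance(model, p, {"all": X}) == pytest.approx(
            sem.fiml_deviance(model, p, {"all": shuffled}), rel=1e-12)

    def test_nonpd_signalled_as_penalty(self):
        def implied(p):
            return {"all": (np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))}
        model = sem.StructuredModel(["x"], np.zeros(1), [(None, None)], implied)
        assert sem.fiml_deviance(model, [0.0], {"all": np.zeros((5, 2))}) > 1e9


class TestFit:
    def test_saturated_recovers_sample_moments(self):
        rng = np.random.default_rng(4)
        X = rng.multivariate_normal([1.0, -0.5], [[2.0, 0.6], [0.6, 1.0]], 500)
        fit = sem.fit_ml(sem.saturated_model(2), {"all": X}, seed=0)
        mu, sigma = fit.model.implied(fit.params)["all"]
        np.testing.assert_allclose(mu, X.mean(0), atol=1e-4)
        np.testing.assert_allclose(sigma, np.cov(X.T, ddof=0), atol=1e-3)

    def test_structured_parameter_recovery(self):
        # two-group ACE model at n=10,000 pairs per group
        cfg = tw.SimulationConfig(10_000, 10_000, 1, ["x"], (0.6, 0.2, 0.2),
                                  seed=6)
        c = tw.simulate_cohort(cfg)
        res = tw.fit_univariate_ace(c, "x", 1, seed=0)
        assert res.converged
        assert res.a2 == pytest.approx(0.6, abs=0.03)
        assert res.c2 == pytest.approx(0.2, abs=0.03)
        assert res.e2 == pytest.approx(0.2, abs=0.01)

    def test_nested_deviance_ordering(self, big_twowave_cohort):
        from twinwaves.twin import fit_ace_submodels
        fits = fit_ace_submodels(big_twowave_cohort, "x", 1, seed=0)
        assert fits["ACE"].deviance <= fits["AE"].deviance + 1e-6
        assert fits["ACE"].deviance <= fits["CE"].deviance + 1e-6

    def test_grid_search_oracle_on_toy_twin_data(self):
        # brute-force grid over (mu, V, a2, c2) confirms the optimizer's optimum
        cfg = tw.SimulationConfig(150, 150, 1, ["x"], (0.5, 0.2, 0.3), seed=7)
        c = tw.simulate_cohort(cfg)
        data = {g: sem.PatternData(X) for g, X in family_table(c, "x", [1]).items()}
        model = _ace_model()
        fit = sem.fit_ml(model, data, seed=0)
        y = c.data["x_t1"].to_numpy()
        best = np.inf
        best_p = None
        for mu in np.linspace(y.mean() - 0.1, y.mean() + 0.1, 5):
            for V in np.linspace(0.8, 1.2, 9) * y.var():
                for a2 in np.linspace(0, 1, 21):
                    for c2 in np.linspace(0, 1 - a2, max(int(21 * (1 - a2)), 1)):
                        d = sem.fiml_deviance(model, [mu, V, a2, c2], data)
                        if d < best:
                            best, best_p = d, (mu, V, a2, c2)
        assert fit.deviance <= best + 1e-6
        assert fit["a2"] == pytest.approx(best_p[2], abs=0.06)


class TestProfileCI:
    def test_quadratic_deviance_matches_wald(self):
        rng = np.random.default_rng(8)
        n = 100
        X = rng.standard_normal((n, 1)) + 0.4
        fit = sem.fit_ml(_fixed_normal_model(1), {"all": X}, seed=0)
        lo, hi = sem.profile_ci(fit, "mu0", 0.95)
        half = stats.norm.ppf(0.975) / np.sqrt(n)
        assert lo == pytest.approx(X.mean() - half, abs=1e-4)
        assert hi == pytest.approx(X.mean() + half, abs=1e-4)

    def test_level_zero_degenerate(self):
        rng = np.random.default_rng(9)
        fit = sem.fit_ml(_fixed_normal_model(1),
                         {"all": rng.standard_normal((30, 1))}, seed=0)
        lo, hi = sem.profile_ci(fit, "mu0", 0.0)
        assert lo == hi == fit["mu0"]

    def test_coverage_on_simulated_ace_models(self):
        reps, cover = 60, 0
        for i in range(reps):
            cfg = tw.SimulationConfig(400, 400, 1, ["x"], (0.4, 0.2, 0.4),
                                      seed=1000 + i)
            c = tw.simulate_cohort(cfg)
            fit = sem.fit_ml(_ace_model(), family_table(c, "x", [1]),
                             n_restarts=2, seed=i)
            lo, hi = sem.profile_ci(fit, "a2", 0.95)
            cover += lo <= 0.4 <= hi
        assert 0.86 <= cover / reps <= 1.0


class TestLRT:
    def test_identical_models(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((50, 1))
        fit = sem.fit_ml(_fixed_normal_model(1), {"all": X}, seed=0)
        res = sem.lrt(fit, fit, df=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_null_distribution_is_chi_square(self):
        # free-mean vs zero-mean Gaussian: LRT ~ chi2(1) under the null
        rng = np.random.default_rng(11)

        def zero_model():
            return sem.StructuredModel(
                ["logv"], np.zeros(1), [(None, None)],
                lambda p: {"all": (np.zeros(1), np.exp(p[:1])[:, None])})

        def free_model():
            return sem.StructuredModel(
                ["mu", "logv"], np.zeros(2), [(None, None)] * 2,
                lambda p: {"all": (p[:1], np.exp(p[1:2])[:, None])})

        stats_ = []
        for _ in range(400):
            X = rng.standard_normal((40, 1))
            full = sem.fit_ml(free_model(), {"all": X}, n_restarts=1)
            nested = sem.fit_ml(zero_model(), {"all": X}, n_restarts=1)
            stats_.append(sem.lrt(full, nested, 1).statistic)
        ks = stats.kstest(stats_, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(12)

        def free_model():
            return sem.StructuredModel(
                ["mu", "logv"], np.zeros(2), [(None, None)] * 2,
                lambda p: {"all": (p[:1], np.exp(p[1:2])[:, None])})

        def zero_model():
            return sem.StructuredModel(
                ["logv"], np.zeros(1), [(None, None)],
                lambda p: {"all": (np.zeros(1), np.exp(p[:1])[:, None])})

        power = []
        for shift in (0.0, 0.3, 0.8):
            rej = 0
            for _ in range(60):
                X = rng.standard_normal((40, 1)) + shift
                full = sem.fit_ml(free_model(), {"all": X}, n_restarts=1)
                nested = sem.fit_ml(zero_model(), {"all": X}, n_restarts=1)
                rej += sem.lrt(full, nested, 1).p_value < 0.05
            power.append(rej / 60)
        assert power[0] < power[1] < power[2]
        assert power[0] < 0.15 and power[2] > 0.9
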