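"""p-factor, GPS regression, extremes contrasts and attrition checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import expit, logit

import twinwaves as tw
from twinwaves.association import (attrition_check, environment_correlates,
                                   extreme_groups, extremes_analysis,
                                   gps_regression, p_factor,
                                   trajectory_contrast)


class TestPFactor:
    def test_identical_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        res = p_factor(np.column_stack([x, x, x]))
        assert res.explained_variance == pytest.approx(1.0, abs=1e-10)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(np.abs(res.scores), np.abs(z), atol=1e-8)

    def test_independent_columns_isotropy(self):
        rng = np.random.default_rng(1)
        res = p_factor(rng.standard_normal((20_000, 5)))
        assert res.explained_variance == pytest.approx(0.2, abs=0.02)

    def test_one_factor_recovery(self):
        rng = np.random.default_rng(2)
        n, m, lam = 5000, 6, 0.6
        f = rng.standard_normal(n)
        X = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, m))
        res = p_factor(X)
        # equal loadings by symmetry: unit-norm vector has entries 1/sqrt(m)
        np.testing.assert_allclose(res.loadings, 1 / np.sqrt(m), atol=0.02)
        assert abs(np.corrcoef(res.scores, f)[0, 1]) > 0.85

    def test_scores_standardized_and_sign_convention(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((300, 4)) + 0.5 * rng.standard_normal((300, 1))
        res = p_factor(X)
        assert np.nanmean(res.scores) == pytest.approx(0.0, abs=1e-10)
        assert np.nanstd(res.scores) == pytest.approx(1.0, abs=1e-10)
        assert res.loadings.mean() > 0
        assert np.linalg.norm(res.loadings) == pytest.approx(1.0, abs=1e-10)

    def test_rescaling_invariance_and_zero_variance_column(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((400, 3)) + rng.standard_normal((400, 1))
        a = p_factor(X)
        Xs = X * np.array([10.0, 0.1, 3.0])
        b = p_factor(Xs)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-8)
        Xz = np.column_stack([X, np.full(400, 7.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            c = p_factor(Xz)
        np.testing.assert_allclose(np.abs(c.scores), np.abs(a.scores), atol=1e-8)


class TestGPSRegression:
    def test_independent_gps_near_zero(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(5000)
        g = rng.standard_normal(5000)
        res = gps_regression(y, g, n_permutations=200, seed=1)
        assert res["delta_r2"] < 0.002
        assert res["p_permutation"] > 0.05

    def test_small_effect_regime(self):
        # net correlation 0.09 -> incremental R^2 just under 1%
        rng = np.random.default_rng(6)
        n = 20_000
        g = rng.standard_normal(n)
        cov = rng.standard_normal(n)
        y = 0.09 * g + 0.3 * cov + np.sqrt(1 - 0.09**2 - 0.09) * \
            rng.standard_normal(n)
        res = gps_regression(y, g, cov.reshape(-1, 1))
        assert res["delta_r2"] == pytest.approx(0.09**2 / (1 - 0.09), rel=0.3)
        assert res["delta_r2"] < 0.01

    def test_delta_r2_equals_squared_partial_correlation(self):
        rng = np.random.default_rng(7)
        n = 800
        C = rng.standard_normal((n, 2))
        g = 0.4 * C[:, 0] + rng.standard_normal(n)
        y = 0.3 * C[:, 1] + 0.2 * g + rng.standard_normal(n)
        res = gps_regression(y, g, C)
        X0 = np.column_stack([np.ones(n), C])
        ry = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
        rg = g - X0 @ np.linalg.lstsq(X0, g, rcond=None)[0]
        partial = np.corrcoef(ry, rg)[0, 1]
        # incremental R^2 = partial^2 * (1 - R^2_covariates)
        expected = partial**2 * (1 - res["r2_covariates"])
        assert res["delta_r2"] == pytest.approx(expected, rel=1e-6)

    def test_collinear_covariates_warn(self):
        rng = np.random.default_rng(8)
        c = rng.standard_normal(100)
        with pytest.warns(UserWarning, match="collinear"):
            gps_regression(rng.standard_normal(100), rng.standard_normal(100),
                           np.column_stack([c, 2 * c]))


class TestExtremeGroups:
    def test_tail_shares_match_normal(self):
        rng = np.random.default_rng(9)
        lab = extreme_groups(rng.standard_normal(100_000))
        tail = stats.norm.cdf(-1)
        assert (lab == "low").mean() == pytest.approx(tail, abs=0.005)
        assert (lab == "high").mean() == pytest.approx(tail, abs=0.005)

    def test_constant_scores_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            lab = extreme_groups(np.zeros(50))
        assert (lab == "mid").all()

    def test_shift_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(1000)
        np.testing.assert_array_equal(extreme_groups(x), extreme_groups(x + 100))


class TestTrajectoryContrast:
    def test_group_blind_simulation_null(self):
        rng = np.random.default_rng(11)
        Y = rng.standard_normal((3000, 4))
        groups = extreme_groups(rng.standard_normal(3000))
        res = trajectory_contrast(Y, groups)
        assert np.abs(res.d).max() < 0.15
        assert res.interaction.p_value > 0.01

    def test_baseline_selection_matches_truncated_normal_oracle(self):
        # selecting tails of the baseline score itself: expected baseline d
        # follows from truncated-normal moments
        rng = np.random.default_rng(12)
        n = 200_000
        base = rng.standard_normal(n)
        Y = np.column_stack([base, rng.standard_normal(n)])
        res = trajectory_contrast(Y, extreme_groups(base))
        h = stats.norm.pdf(1) / stats.norm.sf(1)
        gap = 2 * h
        v = 1 + h - h**2  # Var(Z | Z > 1)
        expected_d = gap / np.sqrt(v)
        assert res.d[0] == pytest.approx(expected_d, rel=0.02)
        assert res.d[1] == pytest.approx(0.0, abs=0.05)

    def test_extremes_pipeline_recovers_designed_t2_gap(self):
        df, _ = tw.simulate_extremes_sample(n=20_000, seed=13)
        out = extremes_analysis(df, [f"m{j}" for j in range(1, 9)], 5)
        assert out["mean_d_per_wave"][1] == pytest.approx(0.47, abs=0.06)
        assert out["mean_d_per_wave"][0] > 1.5  # selection effect at baseline


class TestEnvironmentAndAttrition:
    def test_environment_correlates(self):
        rng = np.random.default_rng(14)
        n = 8000
        env = rng.standard_normal(n)
        pheno = 0.21 * env + np.sqrt(1 - 0.21**2) * rng.standard_normal(n)
        res = environment_correlates(pheno, env)
        assert res["r"] == pytest.approx(0.21, abs=0.03)
        assert res["ci_low"] < 0.21 < res["ci_high"]
        self_r = environment_correlates(env, env.copy() * 2 + 1)
        assert self_r["r"] == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError, match="constant"):
            environment_correlates(np.ones(10), rng.standard_normal(10))

    def test_attrition_check_identity_and_mcar(self):
        cfg = tw.SimulationConfig(2000, 2000, 2, ["x"], seed=15)
        full = tw.simulate_cohort(cfg)
        tab = attrition_check(full, full, ["x_t1"])
        assert tab.std_difference.iloc[0] == 0.0
        cfg2 = tw.SimulationConfig(2000, 2000, 2, ["x"], seed=15,
                                   attrition={"retention": [1.0, 0.5],
                                              "mechanism": "MCAR"})
        thinned = tw.simulate_cohort(cfg2)
        retained = thinned.copy()
        retained.data = retained.data[retained.data["x_t2"].notna()]
        tab2 = attrition_check(full, retained, ["x_t1"])
        assert abs(tab2.std_difference.iloc[0]) < 0.05

    def test_mar_attrition_matches_quadrature_oracle(self):
        # retention prob expit(logit(p) - s*z): E[x | retained] by quadrature
        p, s = 0.6, 1.0
        cfg = tw.SimulationConfig(30_000, 30_000, 2, ["x"], seed=16,
                                  attrition={"retention": [1.0, p],
                                             "mechanism": "MAR",
                                             "mar_slope": s})
        c = tw.simulate_cohort(cfg)
        keep = c.data["x_t2"].notna()

        def w(x):
            return expit(logit(p) - s * x) * stats.norm.pdf(x)

        num = integrate.quad(lambda x: x * w(x), -8, 8)[0]
        den = integrate.quad(w, -8, 8)[0]
        expected = num / den
        assert c.data.loc[keep, "x_t1"].mean() == pytest.approx(expected,
                                                                abs=0.02)
        assert keep.mean() == pytest.approx(den, abs=0.01)
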