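"""NB GLM / GLMM engine: MLE oracles, AICc, dispersion limits, OLS."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from elevcomm.errors import ConfigurationError, FitError
from elevcomm.glm import (
    THETA_CAP,
    aicc,
    fit_nb_glm,
    fit_nb_glm_batch,
    fit_nb_glmm,
    fit_ols,
    nb_loglik,
)

# glmmTMB (nbinom2, Laplace) reference fits on two fixed toys
GLMM_TOY1 = {  # 40 obs, 5 groups; variance collapses to the boundary
    "y": [5, 5, 1, 1, 2, 0, 1, 1, 8, 1, 1, 0, 10, 0, 0, 1, 2, 2, 1, 0,
          3, 1, 1, 0, 7, 2, 8, 4, 2, 1, 3, 1, 0, 8, 5, 4, 10, 3, 2, 0],
    "x": [0.516, 0.768, -0.05, -0.125, -0.714, -0.155, 0.529, -0.172,
          0.24, -0.912, -0.561, -0.592, 0.962, -0.911, -0.569, -0.937,
          0.279, 0.306, -0.309, -0.927, -0.13, -0.657, -0.147, -0.254,
          -0.558, 0.683, 0.385, -0.059, -0.201, -0.782, 0.206, 0.008,
          0.811, 0.938, 0.619, 0.733, -0.008, -0.252, -0.042, 0.062],
    "g": [0] * 8 + [1] * 8 + [2] * 8 + [3] * 8 + [4] * 8,
    "coef": [0.881305, 1.029664],
    "se": [0.150341, 0.280563],
    "theta": 2.267113,
    "loglik": -79.68647,
}
GLMM_TOY2 = {  # 60 obs, 6 groups; genuine between-group variance
    "y": [0, 1, 4, 4, 0, 0, 6, 0, 1, 3, 0, 2, 2, 3, 3, 4, 2, 4, 1, 1,
          6, 9, 7, 0, 14, 4, 2, 4, 14, 12, 26, 3, 3, 1, 3, 2, 4, 12, 9,
          14, 0, 5, 0, 0, 0, 1, 4, 5, 4, 0, 6, 1, 6, 4, 4, 6, 9, 10, 1, 5],
    "x": [0.222, -0.234, 0.2, 0.927, -0.608, -0.326, 0.137, 0.079,
          0.472, -0.138, -0.885, -0.668, 0.515, 0.36, 0.403, -0.789,
          -0.907, 0.864, -0.157, -0.932, -0.56, -0.02, -0.354, -0.794,
          0.653, -0.744, -0.6, -0.66, 0.784, 0.477, 0.556, -0.851,
          -0.736, -0.671, -0.378, -0.732, -0.684, -0.913, -0.301,
          -0.777, -0.69, 0.519, -0.544, -0.075, 0.383, 0.389, 0.697,
          0.706, -0.181, -0.359, 0.807, -0.858, 0.61, 0.546, 0.79,
          0.431, 0.521, 0.655, 0.477, 0.281],
    "g": [0] * 10 + [1] * 10 + [2] * 10 + [3] * 10 + [4] * 10 + [5] * 10,
    "coef": [1.246314, 0.925098],
    "se": [0.308844, 0.186457],
    "variance": 0.511960,
    "theta": 4.319863,
    "loglik": -140.951,
}


def _design(x):
    x = np.asarray(x, dtype=float)
    return np.column_stack([np.ones(len(x)), x])


class TestNbGlm:
    def test_constant_response_mean_exact(self):
        y = np.full(20, 7)
        fit = fit_nb_glm(y, np.ones((20, 1)))
        assert np.exp(fit.coef[0]) == pytest.approx(7.0, rel=1e-9)

    def test_loglik_matches_brute_force_mle(self, rng):
        # oracle: direct numerical maximisation of the NB likelihood
        x = rng.normal(size=20)
        X = _design(x)
        mu = np.exp(0.8 + 0.6 * x)
        y = rng.negative_binomial(1.5, 1.5 / (1.5 + mu))

        def nll(params):
            b0, b1, logt = params
            m = np.exp(np.clip(b0 + b1 * x, -30, 30))
            return -float(nb_loglik(y[:, None], m[:, None], np.exp(logt))[0])

        best = min(
            (
                optimize.minimize(
                    nll, start, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
                )
                for start in ([0.5, 0.5, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, -1.0])
            ),
            key=lambda r: r.fun,
        )
        fit = fit_nb_glm(y, X)
        assert fit.loglik == pytest.approx(-best.fun, abs=1e-4)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=60)
        X = _design(x)
        mu = np.exp(1.0 + 0.5 * x)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        fit = fit_nb_glm(y, X)
        ref = sm.NegativeBinomial(y, X).fit(disp=0)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)
        assert fit.coef == pytest.approx(ref.params[:2], abs=1e-4)
        assert fit.theta == pytest.approx(1 / ref.params[-1], rel=1e-3)

    def test_equidispersed_reaches_poisson_limit(self):
        # var < mean by construction: theta must hit the cap
        y = np.tile([4, 5], 30)
        fit = fit_nb_glm(y, np.ones((60, 1)))
        assert fit.theta == THETA_CAP
        pois = stats.poisson.logpmf(y, y.mean()).sum()
        # at theta = cap the NB likelihood sits within O(mu^2/theta) of Poisson
        assert fit.loglik == pytest.approx(pois, abs=1e-3)

    def test_local_optimality_of_estimates(self, rng):
        x = rng.normal(size=40)
        X = _design(x)
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + np.exp(1 + 0.3 * x)))
        fit = fit_nb_glm(y, X)
        for delta in ([1e-3, 0], [0, 1e-3], [-1e-3, 1e-3]):
            mu = np.exp(X @ (fit.coef + delta))
            perturbed = float(nb_loglik(y[:, None], mu[:, None], fit.theta)[0])
            assert perturbed <= fit.loglik + 1e-10

    def test_all_zero_response_boundary(self):
        with pytest.warns(RuntimeWarning, match="all-zero"):
            fit = fit_nb_glm(np.zeros(15, dtype=int), np.ones((15, 1)))
        assert fit.boundary
        assert fit.loglik == pytest.approx(0.0, abs=1e-6)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([np.ones(10), x, 2 * x])
        with pytest.raises(FitError, match="rank"):
            fit_nb_glm(rng.poisson(3, 10), X)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_nb_glm(np.array([1, -1, 2]), np.ones((3, 1)))

    def test_batch_agrees_with_single_fits(self, rng):
        x = rng.normal(size=50)
        X = _design(x)
        Y = rng.negative_binomial(
            1.0, 1.0 / (1.0 + np.exp(0.5 + 0.4 * x))[:, None] * np.ones(8),
            size=(50, 8),
        )
        _, th, ll, conv = fit_nb_glm_batch(Y, X)
        assert conv.all()
        for col in range(8):
            single = fit_nb_glm(Y[:, col], X)
            assert ll[col] == pytest.approx(single.loglik, abs=1e-6)


class TestAicc:
    def test_direct_formula(self):
        assert aicc(-10, 3, 10) == pytest.approx(30.0)
        assert aicc(0, 1, 100) == pytest.approx(2 + 4 / 98)

    def test_converges_to_aic_for_large_n(self):
        k, ll = 4, -50.0
        aic = -2 * ll + 2 * k
        assert aicc(ll, k, 10**9) == pytest.approx(aic, abs=1e-6)

    @pytest.mark.parametrize("k,n", [(3, 20), (1, 5), (7, 30)])
    def test_strictly_exceeds_aic(self, k, n):
        assert aicc(-5.0, k, n) > -2 * -5.0 + 2 * k

    def test_overparameterised_model_rejected(self):
        with pytest.raises(ConfigurationError, match="over-parameterised"):
            aicc(-5.0, 5, 6)


class TestNbGlmm:
    @pytest.mark.parametrize("toy", [GLMM_TOY1, GLMM_TOY2],
                             ids=["boundary-variance", "real-variance"])
    def test_matches_laplace_reference(self, toy):
        fit = fit_nb_glmm(
            np.array(toy["y"]), _design(toy["x"]), np.array(toy["g"])
        )
        assert fit.coef == pytest.approx(toy["coef"], abs=2e-3)
        assert fit.se == pytest.approx(toy["se"], rel=2e-2)
        assert fit.theta == pytest.approx(toy["theta"], rel=1e-2)
        assert fit.loglik == pytest.approx(toy["loglik"], abs=1e-2)
        if "variance" in toy:
            assert fit.random_variance == pytest.approx(
                toy["variance"], rel=5e-2
            )

    def test_nests_glm_when_variance_vanishes(self, rng):
        # balanced data with no group structure at all
        x = rng.normal(size=48)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + np.exp(1.0 + 0.5 * x)))
        g = np.tile([0, 1, 2, 3], 12)
        mixed = fit_nb_glmm(y, _design(x), g)
        glm = fit_nb_glm(y, _design(x))
        if mixed.random_variance < 1e-4:
            assert mixed.coef == pytest.approx(glm.coef, abs=1e-3)
            assert mixed.loglik == pytest.approx(glm.loglik, abs=1e-3)

    def test_single_group_falls_back_to_glm(self, rng):
        y = rng.poisson(4, 20)
        with pytest.warns(RuntimeWarning, match="single group"):
            fit = fit_nb_glmm(y, np.ones((20, 1)), np.zeros(20))
        assert fit.n_groups == 1
        assert fit.random_variance == 0.0

    def test_covariate_shift_moves_only_intercept(self):
        toy = GLMM_TOY2
        y, g = np.array(toy["y"]), np.array(toy["g"])
        x = np.array(toy["x"])
        base = fit_nb_glmm(y, _design(x), g)
        shifted = fit_nb_glmm(y, _design(x + 10.0), g)
        assert shifted.coef[1] == pytest.approx(base.coef[1], abs=1e-3)
        assert shifted.coef[0] == pytest.approx(
            base.coef[0] - 10.0 * base.coef[1], abs=1e-2
        )


class TestOls:
    def test_perfect_line(self):
        x = np.arange(10.0)
        slope, adj_r2, p = fit_ols(2.0 * x + 1.0, x)
        assert slope == pytest.approx(2.0)
        assert adj_r2 == pytest.approx(1.0)

    def test_constant_response(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            slope, adj_r2, _ = fit_ols(np.ones(10), np.arange(10.0))
        assert slope == 0.0
        assert adj_r2 <= 0.0

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=10)
        y = 1.0 + 0.5 * x + rng.normal(size=10)
        slope, adj_r2, _ = fit_ols(y, x)
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert slope == pytest.approx(beta[1], rel=1e-10)
        assert adj_r2 == pytest.approx(1 - (1 - r2) * 9 / 8, rel=1e-10)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_ols(np.arange(5.0), np.ones(5))
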