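"""Boosting path behavior, ridge closed forms, lasso-Cox, CV tuning."""

import numpy as np
import pytest

from seqsig.boostfit import (
    BoostConfig,
    boost_fit,
    check_kkt,
    cox_newton,
    cox_partial_loglik,
    cv_tune,
    lasso_cox_fit,
    penalty_from_nu,
    ridge_closed_form,
    ridge_standardized,
    _logistic_loglik,
)
from seqsig.errors import InvalidArgumentError


def _orthonormal_design(rng, n, p):
    q, _ = np.linalg.qr(rng.standard_normal((n, p + 1)))
    z = q[:, 1:]  # columns orthogonal to the constant direction -> centered
    z = z - z.mean(axis=0)
    return z / np.linalg.norm(z, axis=0)


def _survival(rng, n, beta, censor_scale=3.0):
    p = len(beta)
    z = rng.standard_normal((n, p))
    t = rng.exponential(1, n) / np.exp(z @ beta)
    c = rng.uniform(0, censor_scale, n)
    return z, np.minimum(t, c), (t <= c).astype(int)


class TestBoostPath:
    def test_first_step_is_stagewise_on_orthonormal_design(self, rng):
        # continuous response, lambda = 0: selection by |Z_j'y|, update = OLS coef
        z = _orthonormal_design(rng, 40, 5)
        y = rng.standard_normal(40)
        y = y - y.mean()
        cfg = BoostConfig(family="gaussian", max_steps=1, penalty=0.0)
        path = boost_fit(z, y, cfg)
        scores = z.T @ y
        j = int(np.argmax(np.abs(scores)))
        assert path.selected[0] == j
        assert np.isclose(path.updates[0], scores[j])  # Z_j'Z_j = 1

    def test_high_variance_covariate_selected_more_often(self, rng):
        # equal standardized association, variances 1 vs 4, lambda > 0
        wins = 0
        for rep in range(40):
            r = np.random.default_rng(rep)
            z1 = r.standard_normal(80)
            z2 = 2.0 * r.standard_normal(80)
            y = 0.3 * (z1 / z1.std()) + 0.3 * (z2 / z2.std()) + r.standard_normal(80)
            z = np.column_stack([z1, z2])
            cfg = BoostConfig(family="gaussian", max_steps=1, penalty=200.0)
            path = boost_fit(z, y - y.mean(), cfg)
            wins += path.selected[0] == 1
        assert wins > 20

    def test_zero_steps_means_zero_coefficients(self, rng):
        z = rng.standard_normal((30, 4))
        y = rng.integers(0, 2, 30)
        path = boost_fit(z, y, BoostConfig(family="logistic", max_steps=0, nu=0.1))
        assert np.all(path.coef == 0) and path.n_steps == 0

    @pytest.mark.parametrize("family", ["gaussian", "logistic", "cox"])
    def test_loglik_nondecreasing_along_path(self, family, rng):
        n, p = 60, 20
        z = rng.standard_normal((n, p))
        if family == "cox":
            _, time, event = _survival(rng, n, np.zeros(3))
            resp = (time, event)
        elif family == "logistic":
            resp = (rng.random(n) < 0.5).astype(int)
        else:
            resp = rng.standard_normal(n)
        path = boost_fit(z, resp, BoostConfig(family=family, max_steps=30, nu=0.1))
        assert np.all(np.diff(path.loglik_path) >= -1e-8)

    def test_mandatory_block_moves_every_step(self, rng):
        n = 80
        z = rng.standard_normal((n, 10))
        eta = 1.5 * z[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        path = boost_fit(z, y, BoostConfig(family="logistic", max_steps=10, nu=0.1, mandatory=(0,)))
        assert 0 not in set(path.selected)
        assert abs(path.coef[0]) > 0.3  # near its unpenalized fit, not boosted from zero

    def test_support_nondecreasing_and_coef_reconstruction(self, rng):
        n = 60
        z = rng.standard_normal((n, 15))
        y = (rng.random(n) < 0.5).astype(int)
        path = boost_fit(z, y, BoostConfig(family="logistic", max_steps=25, nu=0.1))
        supports = path.support_per_step()
        assert all(set(a) <= set(b) for a, b in zip(supports[:-1], supports[1:]))
        icpt, coef = path.coef_at(path.n_steps)
        assert np.allclose(coef, path.coef)

    def test_scale_inflation_raises_selection_frequency(self):
        # a null covariate on a 10x scale is picked first more often
        base_wins, scaled_wins = 0, 0
        for rep in range(30):
            r = np.random.default_rng(1000 + rep)
            z = r.standard_normal((50, 20))
            y = (r.random(50) < 0.5).astype(int)
            cfg = BoostConfig(family="logistic", max_steps=1, nu=0.1)
            base_wins += boost_fit(z, y, cfg).selected[0] == 3
            z2 = z.copy()
            z2[:, 3] *= 10.0
            scaled_wins += boost_fit(z2, y, cfg).selected[0] == 3
        assert scaled_wins > base_wins


class TestRidge:
    def test_lambda_zero_equals_ols(self, rng):
        x = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        beta = ridge_closed_form(x, y, 0.0)
        ols, *_ = np.linalg.lstsq(x, y, rcond=None)
        assert np.allclose(beta, ols, atol=1e-10)

    def test_scaling_identity(self, rng):
        # common-penalty ridge on X = ZD equals D^-1 x standardized ridge
        # with per-covariate penalties lambda / s_j^2
        x = rng.standard_normal((20, 5)) * np.array([0.5, 1.0, 2.0, 5.0, 10.0])
        x = x - x.mean(axis=0)
        y = rng.standard_normal(20)
        lam = 3.0
        s = x.std(axis=0, ddof=1)
        beta_unstd = ridge_closed_form(x, y, lam)
        beta_std = ridge_closed_form(x / s, y, lam / s**2)
        assert np.allclose(beta_unstd, beta_std / s, atol=1e-10)

    def test_equal_variance_penalty_absorbs_scale(self, rng):
        # all covariates share scale s: unstandardized ridge at lambda
        # equals 1/s times standardized ridge at lambda / s^2
        s = 3.0
        z = rng.standard_normal((25, 4))
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
        y = rng.standard_normal(25)
        lam = 2.0
        left = ridge_closed_form(s * z, y, lam)
        right = ridge_closed_form(z, y, lam / s**2) / s
        assert np.allclose(left, right, atol=1e-10)

    def test_shrinkage_to_zero(self, rng):
        x = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        norms = [np.linalg.norm(ridge_closed_form(x, y, lam)) for lam in (0, 1, 10, 100, 1e4)]
        assert all(a >= b for a, b in zip(norms[:-1], norms[1:]))
        assert norms[-1] < 1e-2

    def test_rank_deficient_at_zero_raises(self, rng):
        x = rng.standard_normal((4, 6))
        with pytest.raises(np.linalg.LinAlgError):
            ridge_closed_form(x, rng.standard_normal(4), 0.0)


class TestLassoCox:
    def test_high_penalty_keeps_only_mandatory(self, rng):
        z, time, event = _survival(rng, 80, np.array([0.8, 0.0, 0.0, 0.0]))
        res = lasso_cox_fit(z, time, event, mandatory=(0,), n_alphas=5)
        top = res[0]  # largest penalty first
        assert len(top.selected) == 0
        only_mand = cox_newton(z[:, [0]], time, event)
        assert np.allclose(top.coef[0], only_mand[0], atol=1e-4)

    def test_tiny_penalty_matches_unpenalized_fit(self, rng):
        z, time, event = _survival(rng, 100, np.array([0.7, -0.5, 0.3]), censor_scale=30.0)
        res = lasso_cox_fit(z, time, event, alphas=[1e-7])
        # independent oracle: Newton-Raphson on the partial likelihood
        oracle = cox_newton(z, time, event)
        assert np.allclose(res[0].coef, oracle, atol=1e-4)

    def test_kkt_holds_along_path(self, rng):
        z, time, event = _survival(rng, 70, np.array([0.5, 0.0, 0.0, 0.0, 0.0]))
        pf = np.ones(5)
        for r in lasso_cox_fit(z, time, event, n_alphas=8):
            assert check_kkt(z, time, event, r.coef, r.tuning["alpha"], pf) < 1e-5

    def test_support_grows_as_penalty_decreases(self, rng):
        z, time, event = _survival(rng, 50, np.array([0.8, -0.6, 0.4, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]))
        res = lasso_cox_fit(z, time, event, n_alphas=10)
        sizes = [len(r.selected) for r in res]
        assert sizes[-1] >= sizes[0] and max(sizes) >= 3


class TestCVTune:
    def test_pure_noise_stops_early(self):
        # chosen steps stay within 10% of the budget on null data
        small = 0
        for rep in range(10):
            r = np.random.default_rng(rep)
            z = r.standard_normal((100, 30))
            y = (r.random(100) < 0.5).astype(int)
            steps, _ = cv_tune(z, y, "logistic", method="boost", folds=10, seed=rep, max_steps=100)
            small += steps <= 10
        assert small >= 8

    def test_strong_covariate_survives_cv_stopping(self):
        hits = 0
        for rep in range(5):
            r = np.random.default_rng(100 + rep)
            z = r.standard_normal((80, 15))
            y = (r.random(80) < 1 / (1 + np.exp(-2.0 * z[:, 7]))).astype(int)
            steps, _ = cv_tune(z, y, "logistic", method="boost", folds=5, seed=rep, max_steps=30)
            path = boost_fit(z, y, BoostConfig(family="logistic", max_steps=steps, nu=0.1))
            hits += 7 in set(path.selected)
        assert hits == 5

    def test_leave_one_out_matches_explicit_enumeration(self, rng):
        n, max_steps = 14, 6
        z = rng.standard_normal((n, 3))
        y = np.array([0, 1] * 7)
        steps, curve = cv_tune(z, y, "logistic", method="boost", folds=n, seed=0, max_steps=max_steps)
        # oracle: explicit LOO loop over the same fold structure
        scores = np.zeros((n, max_steps + 1))
        for i in range(n):
            train = np.delete(np.arange(n), i)
            path = boost_fit(z[train], y[train], BoostConfig(family="logistic", max_steps=max_steps, nu=0.1))
            for m in range(max_steps + 1):
                mm = min(m, path.n_steps)
                icpt, coef = path.coef_at(mm)
                eta_i = icpt + z[i] @ coef
                scores[i, m] = _logistic_loglik(y[[i]], np.array([eta_i]))
        assert np.allclose(curve, scores.mean(axis=0))
        assert steps == int(np.argmax(scores.mean(axis=0)))

    def test_lasso_cv_returns_grid_alpha(self, rng):
        z, time, event = _survival(rng, 60, np.array([0.8, 0.0, 0.0, 0.0]))
        alpha, curve = cv_tune(z, (time, event), "cox", method="lasso", folds=5, seed=1, n_alphas=8)
        assert alpha > 0 and np.isfinite(curve).any()


class TestBoostLassoCorrespondence:
    def test_path_matches_soft_thresholding_at_matched_l1(self, rng):
        z = _orthonormal_design(rng, 50, 5)
        beta_true = np.array([2.0, -1.5, 1.0, 0.0, 0.0])
        y = z @ beta_true + 0.1 * rng.standard_normal(50)
        y = y - y.mean()
        cfg = BoostConfig(family="gaussian", max_steps=4000, nu=0.01)
        path = boost_fit(z, y, cfg)
        c = z.T @ y  # OLS coefficients on the orthonormal design

        def soft(lam):
            return np.sign(c) * np.maximum(np.abs(c) - lam, 0.0)

        beta = np.zeros(5)
        checks = 0
        for j, u in zip(path.selected, path.updates):
            beta[j] += u
            l1 = np.abs(beta).sum()
            if l1 < 1e-6 or l1 > 0.98 * np.abs(c).sum():
                continue
            lo, hi = 0.0, np.abs(c).max()
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if np.abs(soft(mid)).sum() > l1:
                    lo = mid
                else:
                    hi = mid
            target = soft(0.5 * (lo + hi))
            assert np.max(np.abs(beta - target)) <= 0.05 * np.abs(c).max()
            checks += 1
        assert checks > 50


def test_penalty_from_nu_conventions(rng):
    y = np.array([0, 1, 1, 0] * 10)
    lam = penalty_from_nu(0.1, "logistic", y)
    assert np.isclose(lam, 9 * 40 * 0.25)
    event = np.array([1, 0, 1, 1, 0])
    assert penalty_from_nu(0.1, "cox", (np.arange(5) + 1.0, event)) == 9 * 3
    assert penalty_from_nu(0.5, "gaussian", np.zeros(20)) == 20


def test_config_validation():
    with pytest.raises(InvalidArgumentError):
        BoostConfig(family="poisson")
    with pytest.raises(InvalidArgumentError):
        BoostConfig(family="cox", penalty=1.0, nu=0.5)
    cfg = BoostConfig(family="cox")
    assert cfg.nu == 0.1


def test_cox_partial_loglik_matches_lifelines(rng):
    import pandas as pd
    from lifelines import CoxPHFitter

    z, time, event = _survival(rng, 60, np.array([0.6, -0.4]))
    beta = cox_newton(z, time, event)
    df = pd.DataFrame(z, columns=["a", "b"])
    df["T"], df["E"] = time, event
    cph = CoxPHFitter().fit(df, "T", "E")
    assert np.allclose(beta, cph.params_.values, atol=1e-5)
    assert np.isclose(
        cox_partial_loglik(z @ beta, time, event), cph.log_likelihood_, rtol=1e-6
    )
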