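"""OLS machinery: stepwise selection, Cook's distance, PRESS chi-squared."""

import numpy as np
import pytest

from kbpkit.regression import (chi_squared_overfit, cooks_distance,
                               externally_studentized_residuals, fit_ols,
                               forward_stepwise, press_statistic,
                               studentized_residuals)


def _design(rng, n, k):
    return rng.standard_normal((n, k))


class TestFitOls:
    def test_hat_sums_to_p(self):
        rng = np.random.default_rng(0)
        for k in (1, 3, 6):
            X = _design(rng, 40, k)
            fit = fit_ols(rng.standard_normal(40), X, [f"x{i}" for i in range(k)])
            assert fit.hat_diag.sum() == pytest.approx(fit.p, abs=1e-9)
            assert np.all((fit.hat_diag >= -1e-12) & (fit.hat_diag <= 1 + 1e-12))

    def test_r2_non_decreasing_with_added_predictor(self):
        rng = np.random.default_rng(1)
        X = _design(rng, 50, 4)
        y = X[:, 0] + rng.standard_normal(50)
        r2 = [fit_ols(y, X[:, :k], [f"x{i}" for i in range(k)]).r_squared
              for k in range(1, 5)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_rank_deficient_raises(self):
        X = np.ones((20, 1))  # collinear with the intercept
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols(np.arange(20.0), X, ["c"])


class TestCooksDistance:
    def test_zero_residual_zero_influence(self):
        x = np.linspace(0, 1, 10)
        fit = fit_ols(2 * x + 1, x[:, None], ["x"])
        np.testing.assert_allclose(cooks_distance(fit), 0.0, atol=1e-16)

    def test_symmetry_of_balanced_design(self):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        y = np.array([0.0, 2.0, 1.0, 3.0])  # equal |residuals| by symmetry
        D = cooks_distance(fit_ols(y, x[:, None], ["x"]))
        assert D[0] == pytest.approx(D[1])
        assert D[2] == pytest.approx(D[3])

    def test_leave_one_out_refit_oracle(self):
        """Hat-matrix formula equals the explicit refit definition."""
        rng = np.random.default_rng(8)
        n, k = 30, 3  # p = 4 with intercept
        X = _design(rng, n, k)
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(n)
        fit = fit_ols(y, X, ["a", "b", "c"])
        D = cooks_distance(fit)
        A = np.column_stack([np.ones(n), X])
        for i in range(n):
            keep = np.arange(n) != i
            coef_i = np.linalg.lstsq(A[keep], y[keep], rcond=None)[0]
            d_oracle = np.sum((fit.fitted - A @ coef_i) ** 2) / (fit.p * fit.s2)
            assert D[i] == pytest.approx(d_oracle, abs=1e-8)

    def test_matches_statsmodels(self):
        """Independent cross-check of D and studentized residuals."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(21)
        X = _design(rng, 25, 2)
        y = X[:, 0] + 0.3 * rng.standard_normal(25)
        fit = fit_ols(y, X, ["a", "b"])
        res = sm.OLS(y, sm.add_constant(X)).fit()
        infl = res.get_influence()
        np.testing.assert_allclose(cooks_distance(fit), infl.cooks_distance[0],
                                   atol=1e-10)
        np.testing.assert_allclose(studentized_residuals(fit),
                                   infl.resid_studentized_internal, atol=1e-10)
        np.testing.assert_allclose(externally_studentized_residuals(fit),
                                   infl.resid_studentized_external, atol=1e-10)


class TestChiSquaredOverfit:
    def test_press_equals_loo_residuals(self):
        rng = np.random.default_rng(10)
        n = 25
        X = _design(rng, n, 2)
        y = X[:, 0] + rng.standard_normal(n)
        fit = fit_ols(y, X, ["a", "b"])
        A = np.column_stack([np.ones(n), X])
        loo = []
        for i in range(n):
            keep = np.arange(n) != i
            coef_i = np.linalg.lstsq(A[keep], y[keep], rcond=None)[0]
            loo.append(y[i] - A[i] @ coef_i)
        assert press_statistic(fit) == pytest.approx(np.sum(np.square(loo)),
                                                     rel=1e-10)

    def test_exact_fit_defined_as_one(self):
        x = np.linspace(0, 1, 30)
        fit = fit_ols(3 * x, x[:, None], ["x"])
        assert chi_squared_overfit(fit) == 1.0

    def test_degenerate_n_rejected(self):
        rng = np.random.default_rng(4)
        X = _design(rng, 5, 3)
        fit = fit_ols(rng.standard_normal(5), X, list("abc"))
        with pytest.raises(ValueError):
            chi_squared_overfit(fit)

    def test_calibration_light(self):
        """Correctly specified fits sit near 1; gross over-fits blow past 1.3."""
        rng = np.random.default_rng(5)
        good = []
        for _ in range(60):
            X = _design(rng, 100, 3)
            y = X @ np.array([1.0, 0.5, -1.0]) + rng.standard_normal(100)
            good.append(chi_squared_overfit(fit_ols(y, X, list("abc"))))
        assert 0.9 < np.mean(good) < 1.1
        over = []
        for _ in range(30):
            X = _design(rng, 40, 36)  # pure noise, p = 37
            y = rng.standard_normal(40)
            over.append(chi_squared_overfit(fit_ols(y, X, [f"x{i}" for i in range(36)])))
        assert np.mean(np.array(over) > 1.3) >= 0.8


class TestForwardStepwise:
    def test_exact_recovery_noise_free(self):
        rng = np.random.default_rng(14)
        X = _design(rng, 40, 4)
        y = 3.0 * X[:, 1]
        fit = forward_stepwise(y, X, ["x1", "x2", "x3", "x4"])
        assert fit.terms == ["x2"]
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_two_term_recovery_with_noise(self):
        rng = np.random.default_rng(15)
        n = 60
        X = _design(rng, n, 4)
        y = 2.0 * X[:, 0] - 1.0 * X[:, 2] + 0.1 * rng.standard_normal(n)
        fit = forward_stepwise(y, X, ["x1", "x2", "x3", "x4"])
        assert set(fit.terms) == {"x1", "x3"}
        idx = {t: i + 1 for i, t in enumerate(fit.terms)}
        se = np.sqrt(fit.s2 * np.diag(fit.xtx_inv))
        assert abs(fit.coef[idx["x1"]] - 2.0) < 3 * se[idx["x1"]]
        assert abs(fit.coef[idx["x3"]] + 1.0) < 3 * se[idx["x3"]]

    def test_null_false_selection_rate(self):
        """With 3 pure-noise candidates at alpha 0.05, a term enters rarely."""
        rng = np.random.default_rng(16)
        selected = 0
        n_seeds = 300
        for _ in range(n_seeds):
            X = _design(rng, 40, 3)
            y = rng.standard_normal(40)
            fit = forward_stepwise(y, X, ["a", "b", "c"], alpha_in=0.05)
            selected += len(fit.terms) > 0
        assert selected / n_seeds <= 0.15

    def test_constant_response_intercept_only(self):
        rng = np.random.default_rng(17)
        X = _design(rng, 30, 3)
        fit = forward_stepwise(np.full(30, 2.5), X, list("abc"))
        assert fit.terms == []
        assert fit.r_squared == 0.0

    def test_interactions_flagged(self):
        rng = np.random.default_rng(18)
        X = _design(rng, 80, 2)
        y = 1.5 * X[:, 0] * X[:, 1] + 0.05 * rng.standard_normal(80)
        fit = forward_stepwise(y, X, ["a", "b"], allow_interactions=True)
        assert "a*b" in fit.terms
        assert "a*b" in fit.flagged_terms

    def test_constant_candidate_skipped(self):
        rng = np.random.default_rng(19)
        X = np.column_stack([np.ones(30), rng.standard_normal(30)])
        y = 2 * X[:, 1] + 0.1 * rng.standard_normal(30)
        fit = forward_stepwise(y, X, ["const", "x"])
        assert fit.terms == ["x"]
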