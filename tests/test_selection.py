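"""Likelihoods, one-step ML, two-step and comparator estimators."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import integrate

import heckmice as hm
from heckmice import (AnalysisModel, Dataset, EstimationError,
                      ExclusionRestrictionWarning, FitOptions, HeckmanParams,
                      HeckmanSpec, UnsupportedMethodError, fit_comparator,
                      fit_heckman_ml, fit_heckman_twostep, loglik_binary,
                      loglik_continuous)
from heckmice.selection import (_binary_nll_grad, _continuous_nll_grad,
                                _likelihood_inputs)
from conftest import simulate


def probit_loglik(endog, exog, coef):
    from scipy.special import log_ndtr
    lin = exog @ coef
    return float(np.sum(log_ndtr(np.where(endog > 0.5, lin, -lin))))


def params_for(spec, rho, sigma=None):
    return HeckmanParams(beta=np.array([0.1, 0.8, -0.4]),
                         beta_s=np.array([0.5, 1.0, -0.5, 1.0]),
                         rho=rho, sigma_eps=sigma)


class TestLoglikBinary:
    def test_rho_zero_factorises_into_two_probits(self, binary_sim, binary_spec):
        data = binary_sim.observed
        params = params_for(binary_spec, rho=0.0)
        ll = loglik_binary(params, data, binary_spec)
        r = data.observed("Y").astype(float)
        Xs = data.design_matrix(binary_spec.selection_covars)
        X = data.design_matrix(binary_spec.outcome_covars)
        y = data.column("Y")
        expected = probit_loglik(r, Xs, params.beta_s) + probit_loglik(
            y[r > 0.5], X[r > 0.5], params.beta)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_single_missing_case_at_zero_index(self):
        values = np.array([[np.nan, 0.0]])
        data = Dataset(values, ["Y", "X1"],
                       {"Y": "binary", "X1": "continuous"}, ~np.isnan(values))
        spec = HeckmanSpec("Y", [], ["X1"], "binary")
        params = HeckmanParams(beta=np.array([0.3]),
                               beta_s=np.array([0.0, 1.0]), rho=0.2)
        # one non-selected case with Xs beta_s = 0 -> log Phi(0) = log 0.5
        assert loglik_binary(params, data, spec) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_term_by_term_quadrature_oracle(self, binary_spec):
        sim = simulate("binary", rho=0.6, n=12, seed=5)
        data = sim.observed
        params = params_for(binary_spec, rho=0.45)
        ll = loglik_binary(params, data, binary_spec)

        def phi2_quad(a, b, r):
            om = 1 - r * r
            f = lambda y, x: np.exp(-(x * x - 2 * r * x * y + y * y) / (2 * om)) / (
                2 * np.pi * np.sqrt(om))
            v, _ = integrate.dblquad(f, -9, a, -9, b, epsabs=1e-12)
            return v

        from scipy.stats import norm
        X = data.design_matrix(binary_spec.outcome_covars)
        Xs = data.design_matrix(binary_spec.selection_covars)
        y, r = data.column("Y"), data.observed("Y")
        expected = 0.0
        for i in range(data.n_cases):
            b = Xs[i] @ params.beta_s
            if not r[i]:
                expected += np.log(norm.cdf(-b))
            else:
                s = 2 * y[i] - 1
                expected += np.log(phi2_quad(s * (X[i] @ params.beta), b, s * params.rho))
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_missing_covariate_raises(self, tiny_dataset):
        spec = HeckmanSpec("Y", ["X1"], ["X1", "X2"], "binary")
        with pytest.raises(EstimationError):
            loglik_binary(params_for(spec, 0.0), tiny_dataset, spec)


class TestLoglikContinuous:
    def test_rho_zero_factorises(self, continuous_sim, continuous_spec):
        data = continuous_sim.observed
        params = params_for(continuous_spec, rho=0.0, sigma=1.3)
        ll = loglik_continuous(params, data, continuous_spec)
        r = data.observed("Y").astype(float)
        Xs = data.design_matrix(continuous_spec.selection_covars)
        X = data.design_matrix(continuous_spec.outcome_covars)
        y = data.column("Y")
        resid = y[r > 0.5] - X[r > 0.5] @ params.beta
        gauss = np.sum(-0.5 * np.log(2 * np.pi) - np.log(params.sigma_eps)
                       - 0.5 * (resid / params.sigma_eps) ** 2)
        expected = probit_loglik(r, Xs, params.beta_s) + gauss
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_one_observed_case_worked_value(self):
        values = np.array([[0.0, 0.0], [np.nan, 10.0]])
        data = Dataset(values, ["Y", "X1"],
                       {"Y": "continuous", "X1": "continuous"}, ~np.isnan(values))
        spec = HeckmanSpec("Y", [], ["X1"], "continuous")
        params = HeckmanParams(beta=np.array([0.0]),
                               beta_s=np.array([0.0, 0.0]), rho=0.0, sigma_eps=1.0)
        # obs case: Y = Xb, Xs bs = 0, rho=0 -> log 0.5 - log sqrt(2 pi);
        # missing case: log Phi(0) = log 0.5
        expected = (np.log(0.5) - 0.5 * np.log(2 * np.pi)) + np.log(0.5)
        assert loglik_continuous(params, data, spec) == pytest.approx(expected, abs=1e-12)

    def test_sigma_must_be_positive(self, continuous_sim, continuous_spec):
        with pytest.raises(ValueError):
            loglik_continuous(params_for(continuous_spec, 0.1, sigma=-1.0),
                              continuous_sim.observed, continuous_spec)


class TestGradients:
    @pytest.mark.parametrize("kind", ["binary", "continuous"])
    def test_analytic_gradient_matches_finite_differences(self, kind, rng):
        n, nm = 80, 30
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        Xs = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        Xm = np.column_stack([np.ones(nm), rng.normal(size=(nm, 3))])
        if kind == "binary":
            s = rng.choice([-1.0, 1.0], n)
            theta = rng.normal(scale=0.4, size=8)
            f = lambda th: _binary_nll_grad(th, X, Xs, s, Xm)
        else:
            y = rng.normal(size=n)
            theta = np.append(rng.normal(scale=0.4, size=8), 0.2)
            f = lambda th: _continuous_nll_grad(th, X, Xs, y, Xm)
        _, g = f(theta)
        h = 1e-6
        for j in range(theta.size):
            e = np.zeros_like(theta)
            e[j] = h
            num = (f(theta + e)[0] - f(theta - e)[0]) / (2 * h)
            assert num == pytest.approx(g[j], rel=1e-5, abs=1e-5)


class TestFitHeckmanML:
    def test_mar_self_consistency_with_observed_data_fits(self, binary_spec):
        # with rho = 0 the ML fit should agree with separate probits
        sim = simulate("binary", rho=0.0, n=5000, seed=3)
        fit = fit_heckman_ml(sim.observed, binary_spec)
        assert fit.converged
        se = np.sqrt(np.diag(fit.psi))
        assert abs(fit.params.rho) < 3 * se[7] * 1.0  # eta scale ~ rho scale at 0
        obs = sim.observed.observed("Y")
        X = sim.observed.design_matrix(["X1", "X2"])[obs]
        y = sim.observed.column("Y")[obs]
        probit = sm.Probit(y, X).fit(disp=0)
        assert np.allclose(fit.params.beta, probit.params, atol=3 * np.max(probit.bse))

    @pytest.mark.parametrize("kind", ["binary", "continuous"])
    def test_likelihood_at_optimum_beats_truth(self, kind):
        truth_ll, opt_ll = [], []
        spec = HeckmanSpec("Y", ["X1", "X2"], ["X1", "X2", "X3"], kind)
        wins = 0
        for seed in range(12):
            sim = simulate(kind, rho=0.3, n=500, seed=100 + seed)
            fit = fit_heckman_ml(sim.observed, spec)
            truth = HeckmanParams(beta=np.array([0.0, 1.0, 1.0]),
                                  beta_s=np.array([0.75, 1.0, -0.5, 1.0]),
                                  rho=0.3, sigma_eps=None if kind == "binary" else 1.0)
            ll_true = (loglik_binary if kind == "binary" else loglik_continuous)(
                truth, sim.observed, spec)
            wins += fit.loglik >= ll_true - 1e-9
        assert wins >= 11  # ML optimum should dominate the generating values

    def test_case_order_invariance(self, binary_sim, binary_spec):
        fit1 = fit_heckman_ml(binary_sim.observed, binary_spec)
        perm = np.random.default_rng(0).permutation(binary_sim.observed.n_cases)
        d = binary_sim.observed
        shuffled = Dataset(d.values[perm], list(d.var_names), dict(d.var_kinds),
                           d.obs_mask[perm])
        fit2 = fit_heckman_ml(shuffled, binary_spec)
        assert np.allclose(fit1.theta_uncon, fit2.theta_uncon, atol=1e-6)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)

    def test_psi_symmetric_positive_semidefinite(self, binary_sim, binary_spec):
        fit = fit_heckman_ml(binary_sim.observed, binary_spec)
        assert np.allclose(fit.psi, fit.psi.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.psi) > -1e-12)
        assert fit.psi.shape[0] == fit.theta_uncon.size

    def test_requires_both_observed_and_missing_outcomes(self, binary_spec):
        sim = simulate("binary", rho=0.0, n=200, seed=1)
        full = sim.full
        with pytest.raises(EstimationError):
            fit_heckman_ml(full, binary_spec)

    def test_too_few_cases_raises(self, binary_spec):
        sim = simulate("binary", rho=0.0, n=500, seed=2)
        d = sim.observed
        # keep 5 cases (fewer than the 8 parameters), with >=1 obs and missing
        r = d.observed("Y")
        keep = np.concatenate([np.flatnonzero(r)[:3], np.flatnonzero(~r)[:2]])
        small = Dataset(d.values[keep], list(d.var_names), dict(d.var_kinds),
                        d.obs_mask[keep])
        with pytest.raises(EstimationError):
            fit_heckman_ml(small, binary_spec)

    def test_drops_cases_with_missing_covariates(self, binary_spec):
        cfg = hm.ScenarioConfig(outcome_kind="binary", rho=0.6, n=600,
                                x2_missing="mech_A")
        sim = hm.generate_replicate(cfg, np.random.default_rng(9), x2_intercept=0.75)
        fit = fit_heckman_ml(sim.observed, binary_spec)
        assert fit.n_used == int(sim.observed.observed("X2").sum())
        assert fit.converged

    def test_summary_reports_natural_scale(self, continuous_sim, continuous_spec):
        fit = fit_heckman_ml(continuous_sim.observed, continuous_spec)
        tab = fit.summary()
        assert list(tab["term"])[:3] == ["(Intercept)", "X1", "X2"]
        assert {"rho", "sigma_eps"} <= set(tab["term"])
        row = tab[tab["term"] == "rho"].iloc[0]
        assert -1 < row["estimate"] < 1
        assert row["se"] > 0


class TestTwoStep:
    def test_refuses_binary_outcomes(self, binary_sim, binary_spec):
        with pytest.raises(UnsupportedMethodError, match="not valid for binary"):
            fit_heckman_twostep(binary_sim.observed, binary_spec)

    def test_lambda_coefficient_near_zero_under_mar(self, continuous_spec):
        sim = simulate("continuous", rho=0.0, n=5000, seed=21)
        fit = fit_heckman_twostep(sim.observed, continuous_spec)
        # rho*sigma is the coefficient on the Mills ratio; ~0 under MAR
        rs = fit.params.rho * fit.params.sigma_eps
        assert abs(rs) < 0.12  # ~3 SE at this n

    def test_agrees_with_ml_at_large_n(self, continuous_spec):
        sim = simulate("continuous", rho=0.6, n=100_000, seed=22)
        ml = fit_heckman_ml(sim.observed, continuous_spec)
        ts = fit_heckman_twostep(sim.observed, continuous_spec)
        assert np.max(np.abs(ml.params.beta - ts.params.beta)) <= 0.01
        assert ts.params.rho == pytest.approx(0.6, abs=0.05)
        assert ts.params.sigma_eps == pytest.approx(1.0, abs=0.03)

    def test_psi_shape_and_psd(self, continuous_sim, continuous_spec):
        fit = fit_heckman_twostep(continuous_sim.observed, continuous_spec)
        assert fit.psi.shape == (fit.theta_uncon.size,) * 2
        assert np.all(np.linalg.eigvalsh(fit.psi) > -1e-12)


class TestComparators:
    def test_before_and_cca_identical_without_missingness(self, binary_spec):
        sim = simulate("binary", rho=0.3, n=400, seed=31)
        analysis = AnalysisModel("Y", ["X1", "X2"], "binary")
        a = fit_comparator(sim.full, "before-deletion", analysis)
        b = fit_comparator(sim.full, "cca", analysis)
        assert np.allclose(a["estimate"], b["estimate"])
        assert np.allclose(a["se"], b["se"])

    def test_cca_drops_listwise(self, tiny_dataset):
        analysis = AnalysisModel("Y", ["X1"], "binary")
        tab = fit_comparator(tiny_dataset, "cca", analysis)
        assert len(tab) == 2  # intercept + X1

    def test_unknown_method_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            fit_comparator(tiny_dataset, "drop-everything",
                           AnalysisModel("Y", ["X1"], "binary"))


class TestSpecValidation:
    def test_exclusion_restriction_warning(self):
        with pytest.warns(ExclusionRestrictionWarning):
            HeckmanSpec("Y", ["X1", "X2"], ["X1", "X2"], "binary")

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            HeckmanSpec("Y", ["X1", "X1"], ["X1", "X3"], "binary")

    def test_binary_values_validated(self):
        values = np.array([[2.0, 0.1]])
        with pytest.raises(ValueError):
            Dataset(values, ["Y", "X1"], {"Y": "binary", "X1": "continuous"},
                    np.ones_like(values, dtype=bool))
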