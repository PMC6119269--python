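"""Heckman (Tobit type-2, sample-selection) models for outcomes that are
missing not at random.

A sample-selection model couples an outcome equation with a probit *selection*
equation for the missingness indicator ``R`` (``R = 1`` means observed) through
bivariate-normal latent errors with correlation ``rho``:

.. math::

    R'_i = X^s_i \\beta^s + \\varepsilon^s_i, \\qquad
    Y'_i = X_i \\beta + \\varepsilon_i, \\qquad
    (\\varepsilon^s, \\varepsilon) \\sim N_2(0, \\Sigma),

with ``Var(eps_s) = 1`` and, for a continuous outcome,
``Var(eps) = sigma_eps**2`` and ``Cov = rho * sigma_eps``.  ``rho = 0`` is MAR;
``rho != 0`` makes the missingness depend on the unseen outcome (MNAR).

This module provides the distributional primitives (bivariate-normal CDF,
inverse Mills ratio), the one-step maximum-likelihood estimators for binary and
continuous outcomes, the classical two-step (Heckit) estimator for continuous
outcomes, and plain probit/least-squares comparators.  Fits are parameterised
on an unconstrained scale ``theta = (beta, beta_s, atanh(rho)[, log(sigma)])``
so that Gaussian parameter draws made by the imputation layer always map back
to valid parameters.

A two-step estimator for *binary* outcomes (a probit adjusted on the inverse
Mills ratio) is intentionally refused: selection does not enter a non-linear
outcome model as an additive regressor, so that construction is invalid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from scipy.stats import norm

logger = logging.getLogger("heckmice")

# Cap on |atanh(rho)| during optimisation: beyond it (|rho| > 0.9999) the
# information matrix is numerically degenerate and the fit is flagged
# non-convergent rather than trusted.
ATANH_RHO_CAP = 5.0

_LOG_FLOOR = 1e-300

_INV_SQRT_2PI = 0.3989422804014327
_ndtr = special.ndtr


def _npdf(x):
    return np.exp(-0.5 * x * x) * _INV_SQRT_2PI


class EstimationError(RuntimeError):
    """Raised when a model cannot be estimated (too few cases, singularities)."""


class UnsupportedMethodError(ValueError):
    """Raised for requests the methodology forbids (e.g. binary two-step)."""


class ExclusionRestrictionWarning(UserWarning):
    """Selection equation contains no covariate absent from the outcome equation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """A rectangular case-by-variable table with a missingness mask.

    Parameters
    ----------
    values : (n_cases, n_vars) float array; entries at unobserved cells are
        ignored (conventionally NaN).
    var_names : variable identifiers, one per column.
    var_kinds : per-variable tag, ``"binary"`` or ``"continuous"``.
    obs_mask : boolean array, same shape as ``values``; True = observed.
        This is where the missingness indicators (R) live.
    """

    values: np.ndarray
    var_names: list[str]
    var_kinds: dict[str, str]
    obs_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.obs_mask = np.asarray(self.obs_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cases x variables)")
        if self.obs_mask.shape != self.values.shape:
            raise ValueError("obs_mask shape must equal values shape")
        if self.values.shape[1] != len(self.var_names):
            raise ValueError("var_names length must match number of columns")
        if self.n_cases < 1:
            raise ValueError("dataset needs at least one case")
        for name in self.var_names:
            if self.var_kinds.get(name) not in ("binary", "continuous"):
                raise ValueError(f"variable {name!r} needs kind binary|continuous")
        for name in self.var_names:
            if self.var_kinds[name] == "binary":
                col = self.column(name)
                obs = col[self.observed(name)]
                if obs.size and not np.isin(obs, (0.0, 1.0)).all():
                    raise ValueError(f"binary variable {name!r} has values outside {{0,1}}")

    # -- accessors ----------------------------------------------------------

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    def index(self, name: str) -> int:
        try:
            return self.var_names.index(name)
        except ValueError:
            raise KeyError(f"no variable named {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.index(name)]

    def observed(self, name: str) -> np.ndarray:
        """Boolean observedness indicator (R) for one variable."""
        return self.obs_mask[:, self.index(name)]

    def is_complete(self, name: str) -> bool:
        return bool(self.observed(name).all())

    def design_matrix(self, covars: list[str]) -> np.ndarray:
        """Covariate matrix with a leading intercept column."""
        cols = [np.ones(self.n_cases)]
        cols.extend(self.column(c) for c in covars)
        return np.column_stack(cols)

    def copy(self) -> "Dataset":
        return Dataset(self.values.copy(), list(self.var_names),
                       dict(self.var_kinds), self.obs_mask.copy())

    # -- pandas bridges -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       var_kinds: dict[str, str] | None = None) -> "Dataset":
        """Build from a DataFrame; NaN marks missing.  Kinds are inferred
        (observed values all in {0,1} -> binary) unless supplied."""
        values = df.to_numpy(dtype=float)
        mask = ~np.isnan(values)
        names = [str(c) for c in df.columns]
        kinds = dict(var_kinds or {})
        for j, name in enumerate(names):
            if name not in kinds:
                obs = values[mask[:, j], j]
                kinds[name] = ("binary" if obs.size and np.isin(obs, (0.0, 1.0)).all()
                               else "continuous")
        return cls(values, names, kinds, mask)

    def to_dataframe(self) -> pd.DataFrame:
        out = self.values.copy()
        out[~self.obs_mask] = np.nan
        return pd.DataFrame(out, columns=self.var_names)


@dataclass
class HeckmanSpec:
    """Covariate sets of the outcome and selection equations.

    Intercepts are implied and never listed.  The selection equation should
    contain at least one covariate absent from the outcome equation (the
    exclusion restriction); otherwise the model is identified only through the
    non-linearity of the inverse Mills ratio and a warning is emitted.
    """

    outcome_var: str
    outcome_covars: list[str]
    selection_covars: list[str]
    outcome_kind: str  # "binary" | "continuous"

    def __post_init__(self) -> None:
        if self.outcome_kind not in ("binary", "continuous"):
            raise ValueError("outcome_kind must be binary|continuous")
        for lst, tag in ((self.outcome_covars, "outcome"), (self.selection_covars, "selection")):
            if len(set(lst)) != len(lst):
                raise ValueError(f"duplicate covariates in the {tag} equation")
        if self.outcome_var in self.outcome_covars or self.outcome_var in self.selection_covars:
            raise ValueError("outcome variable cannot appear among its own covariates")
        if not set(self.selection_covars) - set(self.outcome_covars):
            warnings.warn(
                "selection equation has no covariate absent from the outcome "
                "equation; the exclusion restriction is violated and estimates "
                "may be unstable", ExclusionRestrictionWarning, stacklevel=2)


@dataclass
class HeckmanParams:
    """Natural-scale parameters of a sample-selection model."""

    beta: np.ndarray          # outcome coefficients incl. intercept
    beta_s: np.ndarray        # selection coefficients incl. intercept
    rho: float
    sigma_eps: float | None = None  # continuous outcomes only

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.beta_s = np.asarray(self.beta_s, dtype=float)
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma_eps is not None and not self.sigma_eps > 0:
            raise ValueError("sigma_eps must be > 0")


@dataclass
class HeckmanFit:
    """A fitted sample-selection model on the unconstrained scale.

    ``theta_uncon`` stacks (beta, beta_s, atanh rho[, log sigma_eps]); ``psi``
    is its variance-covariance matrix, the input to proper imputation draws.
    """

    params: HeckmanParams
    theta_uncon: np.ndarray
    psi: np.ndarray | None
    loglik: float
    converged: bool
    n_used: int
    spec: HeckmanSpec
    estimator: str = "ml"  # "ml" | "twostep"

    def summary(self) -> pd.DataFrame:
        """Plain coefficient table; rho and sigma_eps on the natural scale
        with delta-method SEs."""
        p = self.params
        terms = (["(Intercept)"] + self.spec.outcome_covars
                 + ["s(Intercept)"] + [f"s({c})" for c in self.spec.selection_covars]
                 + ["rho"])
        est = np.concatenate([p.beta, p.beta_s, [p.rho]])
        jac = np.ones(self.theta_uncon.size)
        jac[p.beta.size + p.beta_s.size] = 1.0 - p.rho ** 2  # d tanh / d eta
        if p.sigma_eps is not None:
            terms.append("sigma_eps")
            est = np.append(est, p.sigma_eps)
            jac[-1] = p.sigma_eps  # d exp / d log
        if self.psi is not None:
            se = np.sqrt(np.diag(self.psi)) * jac
        else:
            se = np.full(est.size, np.nan)
        z = est / se
        lo, hi = est - 1.959963984540054 * se, est + 1.959963984540054 * se
        return pd.DataFrame({"term": terms, "estimate": est, "se": se,
                             "z": z, "ci_low": lo, "ci_high": hi})


@dataclass
class FitOptions:
    """Tuning knobs for the one-step ML optimiser."""

    maxiter: int = 500
    gtol: float = 1e-6
    atanh_rho_cap: float = ATANH_RHO_CAP
    start: np.ndarray | None = None   # warm start on the unconstrained scale
    hess_inv0: np.ndarray | None = None  # warm BFGS inverse-Hessian seed
    bound_rho: bool = False           # constrain |atanh rho| <= cap (L-BFGS-B)
    vcov: str = "observed"            # "observed" (FD Hessian) | "opg" (BHHH)
    retry_on_failure: bool = True
    hessian_step: float = 1e-5


# ---------------------------------------------------------------------------
# Distributional primitives
# ---------------------------------------------------------------------------


def _bvn_fast(h, k, r):
    """Owen's-T evaluation of the bivariate-normal CDF for finite arrays with
    |r| < 1.  Division by a zero threshold produces +/-inf Owen arguments,
    whose limits owens_t evaluates exactly; the doubly-zero corner is patched
    with its arcsine closed form."""
    d = np.sqrt(1.0 - r * r)
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (k - r * h) / (h * d)
        a2 = (h - r * k) / (k * d)
    t1 = special.owens_t(h, np.nan_to_num(a1))
    t2 = special.owens_t(k, np.nan_to_num(a2))
    hk = h * k
    beta = 0.5 * ((hk < 0) | ((hk == 0) & (h + k < 0)))
    p = 0.5 * (_ndtr(h) + _ndtr(k)) - t1 - t2 - beta
    zz = (h == 0) & (k == 0)
    if np.any(zz):
        p = np.where(zz, 0.25 + np.arcsin(r * np.ones_like(p)) / (2.0 * np.pi), p)
    return np.clip(p, 0.0, 1.0)


def bvn_cdf(a, b, rho):
    """Standard bivariate-normal CDF ``P(Z1 <= a, Z2 <= b)``.

    Evaluated through Owen's T function, which is accurate to near machine
    precision; zero thresholds and ``|rho| = 1`` use closed forms.  Broadcasts
    over array inputs; ``+/-inf`` thresholds are honoured.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1):
        raise ValueError("|rho| must be <= 1")
    a, b, rho = np.broadcast_arrays(a, b, rho)
    out = np.empty(a.shape, dtype=float)

    flat_a, flat_b, flat_r = a.ravel(), b.ravel(), rho.ravel()
    res = np.empty(flat_a.shape)

    # Degenerate correlations.
    hi = flat_r >= 1.0
    lo = flat_r <= -1.0
    res[hi] = _ndtr(np.minimum(flat_a[hi], flat_b[hi]))
    res[lo] = np.maximum(0.0, _ndtr(flat_a[lo]) + _ndtr(flat_b[lo]) - 1.0)

    mid = ~(hi | lo)
    h, k, r = flat_a[mid], flat_b[mid], flat_r[mid]
    val = np.empty(h.shape)

    inf_h = np.isinf(h)
    inf_k = np.isinf(k)
    fin = ~(inf_h | inf_k)
    # Infinite thresholds reduce to a marginal (or zero); norm.cdf handles
    # the doubly-infinite corner.
    val[inf_h] = np.where(h[inf_h] > 0, _ndtr(k[inf_h]), 0.0)
    val[inf_k & ~inf_h] = np.where(k[inf_k & ~inf_h] > 0,
                                   _ndtr(h[inf_k & ~inf_h]), 0.0)

    val[fin] = _bvn_fast(h[fin], k[fin], r[fin])
    res[mid] = np.clip(val, 0.0, 1.0)
    out.ravel()[:] = res
    return out if out.ndim else float(out)


def bvn_pdf(a, b, rho):
    """Standard bivariate-normal density at (a, b)."""
    om = 1.0 - rho * rho
    q = (a * a - 2.0 * rho * a * b + b * b) / om
    return np.exp(-0.5 * q) / (2.0 * np.pi * np.sqrt(om))


def inverse_mills_ratio(t):
    """phi(t) / Phi(t), evaluated in log space so the deep left tail
    (t << 0) neither overflows nor loses precision."""
    t = np.asarray(t, dtype=float)
    out = np.exp(-0.5 * t * t - 0.5 * np.log(2.0 * np.pi) - special.log_ndtr(t))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Log-likelihoods (one-step estimators)
# ---------------------------------------------------------------------------


_RHO_CLIP = 1.0 - 1e-12  # keeps sqrt(1 - rho^2) > 0 when tanh saturates


def _split_theta(theta, p, q, continuous):
    beta = theta[:p]
    beta_s = theta[p:p + q]
    eta = theta[p + q]
    rho = float(np.clip(np.tanh(eta), -_RHO_CLIP, _RHO_CLIP))
    sigma = np.exp(theta[p + q + 1]) if continuous else None
    return beta, beta_s, rho, sigma


def _binary_nll_grad(theta, X_obs, Xs_obs, s_obs, Xs_mis):
    """Negative log-likelihood and gradient of the bivariate-probit
    selection model, on theta = (beta, beta_s, atanh rho)."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        return _binary_nll_grad_impl(theta, X_obs, Xs_obs, s_obs, Xs_mis)


def _binary_nll_grad_impl(theta, X_obs, Xs_obs, s_obs, Xs_mis):
    p, q = X_obs.shape[1], Xs_obs.shape[1]
    beta, beta_s, rho, _ = _split_theta(theta, p, q, continuous=False)

    grad = np.zeros_like(theta)
    ll = 0.0

    # Missing cases: log Phi(-Xs beta_s)
    if Xs_mis.shape[0]:
        b_mis = Xs_mis @ beta_s
        ll += special.log_ndtr(-b_mis).sum()
        w = -inverse_mills_ratio(-b_mis)  # d/db log Phi(-b)
        grad[p:p + q] += Xs_mis.T @ w

    # Observed cases: log Phi2(s*Xb, Xs*bs, s*rho)
    if X_obs.shape[0]:
        a = s_obs * (X_obs @ beta)
        b = Xs_obs @ beta_s
        r = s_obs * rho
        P = np.maximum(_bvn_fast(a, b, r), _LOG_FLOOR)
        ll += np.log(P).sum()

        om = np.sqrt(1.0 - rho * rho)
        dA = _npdf(a) * _ndtr((b - r * a) / om)
        dB = _npdf(b) * _ndtr((a - r * b) / om)
        dR = bvn_pdf(a, b, r)
        grad[:p] += X_obs.T @ (s_obs * dA / P)
        grad[p:p + q] += Xs_obs.T @ (dB / P)
        grad[p + q] += np.sum(s_obs * dR / P) * (1.0 - rho * rho)

    return -ll, -grad


def _continuous_nll_grad(theta, X_obs, Xs_obs, y_obs, Xs_mis):
    """Negative log-likelihood and gradient of the continuous one-step
    estimator, on theta = (beta, beta_s, atanh rho, log sigma)."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        return _continuous_nll_grad_impl(theta, X_obs, Xs_obs, y_obs, Xs_mis)


def _continuous_nll_grad_impl(theta, X_obs, Xs_obs, y_obs, Xs_mis):
    p, q = X_obs.shape[1], Xs_obs.shape[1]
    beta, beta_s, rho, sigma = _split_theta(theta, p, q, continuous=True)

    grad = np.zeros_like(theta)
    ll = 0.0

    if Xs_mis.shape[0]:
        b_mis = Xs_mis @ beta_s
        ll += special.log_ndtr(-b_mis).sum()
        grad[p:p + q] += Xs_mis.T @ (-inverse_mills_ratio(-b_mis))

    if X_obs.shape[0]:
        om = np.sqrt(1.0 - rho * rho)
        z = (y_obs - X_obs @ beta) / sigma
        b = Xs_obs @ beta_s
        u = (b + rho * z) / om
        ll += (special.log_ndtr(u)
               - 0.5 * np.log(2.0 * np.pi) - np.log(sigma) - 0.5 * z * z).sum()

        M = inverse_mills_ratio(u)
        grad[:p] += X_obs.T @ ((z - M * rho / om) / sigma)
        grad[p:p + q] += Xs_obs.T @ (M / om)
        # d/d eta via d rho/d eta = 1 - rho^2
        grad[p + q] += np.sum(M * (z + rho * b)) / om
        # d/d log sigma via d sigma/d log sigma = sigma
        grad[p + q + 1] += np.sum(-M * rho * z / om - 1.0 + z * z)

    return -ll, -grad




def _binary_scores(theta, X_obs, Xs_obs, s_obs, Xs_mis):
    """Per-case score rows of the binary joint log-likelihood (cases with the
    outcome observed first, then missing-outcome cases)."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        p, q = X_obs.shape[1], Xs_obs.shape[1]
        beta, beta_s, rho, _ = _split_theta(theta, p, q, continuous=False)
        S = np.zeros((X_obs.shape[0] + Xs_mis.shape[0], theta.size))
        n_obs = X_obs.shape[0]
        if n_obs:
            a = s_obs * (X_obs @ beta)
            b = Xs_obs @ beta_s
            r = s_obs * rho
            P = np.maximum(_bvn_fast(a, b, r), _LOG_FLOOR)
            om = np.sqrt(1.0 - rho * rho)
            dA = _npdf(a) * _ndtr((b - r * a) / om)
            dB = _npdf(b) * _ndtr((a - r * b) / om)
            dR = bvn_pdf(a, b, r)
            S[:n_obs, :p] = X_obs * (s_obs * dA / P)[:, None]
            S[:n_obs, p:p + q] = Xs_obs * (dB / P)[:, None]
            S[:n_obs, p + q] = s_obs * dR / P * (1.0 - rho * rho)
        if Xs_mis.shape[0]:
            b_mis = Xs_mis @ beta_s
            S[n_obs:, p:p + q] = Xs_mis * (-inverse_mills_ratio(-b_mis))[:, None]
        return S


def _continuous_scores(theta, X_obs, Xs_obs, y_obs, Xs_mis):
    """Per-case score rows of the continuous joint log-likelihood."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        p, q = X_obs.shape[1], Xs_obs.shape[1]
        beta, beta_s, rho, sigma = _split_theta(theta, p, q, continuous=True)
        S = np.zeros((X_obs.shape[0] + Xs_mis.shape[0], theta.size))
        n_obs = X_obs.shape[0]
        if n_obs:
            om = np.sqrt(1.0 - rho * rho)
            z = (y_obs - X_obs @ beta) / sigma
            b = Xs_obs @ beta_s
            u = (b + rho * z) / om
            M = inverse_mills_ratio(u)
            S[:n_obs, :p] = X_obs * ((z - M * rho / om) / sigma)[:, None]
            S[:n_obs, p:p + q] = Xs_obs * (M / om)[:, None]
            S[:n_obs, p + q] = M * (z + rho * b) / om
            S[:n_obs, p + q + 1] = -M * rho * z / om - 1.0 + z * z
        if Xs_mis.shape[0]:
            b_mis = Xs_mis @ beta_s
            S[n_obs:, p:p + q] = Xs_mis * (-inverse_mills_ratio(-b_mis))[:, None]
        return S


def _likelihood_inputs(data: Dataset, spec: HeckmanSpec):
    """Design matrices restricted to complete-covariate cases.

    Cases with any missing covariate (outcome or selection equation) are
    dropped — the complete-predictors behaviour of the direct estimators.
    """
    covars = list(dict.fromkeys(spec.outcome_covars + spec.selection_covars))
    usable = np.ones(data.n_cases, dtype=bool)
    for c in covars:
        usable &= data.observed(c)
    r = data.observed(spec.outcome_var) & usable
    X = data.design_matrix(spec.outcome_covars)
    Xs = data.design_matrix(spec.selection_covars)
    y = data.column(spec.outcome_var)
    obs = r
    mis = usable & ~data.observed(spec.outcome_var)
    return (X[obs], Xs[obs], y[obs], Xs[mis], int(usable.sum()))


def loglik_binary(params: HeckmanParams, data: Dataset, spec: HeckmanSpec) -> float:
    """Joint bivariate-probit log-likelihood at the given parameters."""
    if spec.outcome_kind != "binary":
        raise ValueError("spec.outcome_kind must be binary")
    X_obs, Xs_obs, y_obs, Xs_mis, _ = _checked_inputs(data, spec)
    theta = np.concatenate([params.beta, params.beta_s, [np.arctanh(params.rho)]])
    s = 2.0 * y_obs - 1.0
    nll, _ = _binary_nll_grad(theta, X_obs, Xs_obs, s, Xs_mis)
    return -nll


def loglik_continuous(params: HeckmanParams, data: Dataset, spec: HeckmanSpec) -> float:
    """Continuous one-step log-likelihood at the given parameters."""
    if spec.outcome_kind != "continuous":
        raise ValueError("spec.outcome_kind must be continuous")
    if params.sigma_eps is None or params.sigma_eps <= 0:
        raise ValueError("sigma_eps must be positive for continuous outcomes")
    X_obs, Xs_obs, y_obs, Xs_mis, _ = _checked_inputs(data, spec)
    theta = np.concatenate([params.beta, params.beta_s,
                            [np.arctanh(params.rho), np.log(params.sigma_eps)]])
    nll, _ = _continuous_nll_grad(theta, X_obs, Xs_obs, y_obs, Xs_mis)
    return -nll


def _checked_inputs(data, spec):
    covars = list(dict.fromkeys(spec.outcome_covars + spec.selection_covars))
    for c in covars:
        if not data.is_complete(c):
            raise EstimationError(
                f"covariate {c!r} has missing values among cases entering the "
                "likelihood; drop or impute those cases first")
    return _likelihood_inputs(data, spec)


# ---------------------------------------------------------------------------
# One-step maximum-likelihood estimator
# ---------------------------------------------------------------------------


def _probit_start(endog, exog):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Probit(endog, exog).fit(disp=0, maxiter=100)
        coef = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(coef)):
            return coef
    except Exception:  # pragma: no cover - statsmodels failure path
        pass
    return np.zeros(exog.shape[1])


def _start_values(X_obs, Xs_obs, y_obs, Xs_mis, binary):
    n_obs, n_mis = X_obs.shape[0], Xs_mis.shape[0]
    r = np.concatenate([np.ones(n_obs), np.zeros(n_mis)])
    Xs_all = np.vstack([Xs_obs, Xs_mis])
    beta_s0 = _probit_start(r, Xs_all)
    if binary:
        beta0 = _probit_start(y_obs, X_obs)
        return np.concatenate([beta0, beta_s0, [0.0]])
    beta0, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta0
    dof = max(n_obs - X_obs.shape[1], 1)
    sigma0 = max(np.sqrt(resid @ resid / dof), 1e-6)
    return np.concatenate([beta0, beta_s0, [0.0, np.log(sigma0)]])


def _fd_hessian(grad_fn, theta, step):
    d = theta.size
    H = np.empty((d, d))
    for j in range(d):
        h = step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _psd_inverse(H):
    """Inverse of H after clipping eigenvalues at 1e-10 (keeps psi PSD)."""
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, 1e-10)
    return (V / w) @ V.T


def fit_heckman_ml(data: Dataset, spec: HeckmanSpec,
                   options: FitOptions | None = None) -> HeckmanFit:
    """One-step maximum-likelihood fit of the sample-selection model.

    Maximises the joint likelihood over ``(beta, beta_s, atanh rho[, log
    sigma])`` by quasi-Newton with the analytic gradient.  ``psi`` is the
    inverse observed information, obtained by central finite differences of
    the gradient at the optimum.  Cases with missing covariates are dropped
    (complete-predictors behaviour); both observed- and missing-outcome cases
    contribute to the likelihood.
    """
    options = options or FitOptions()
    binary = spec.outcome_kind == "binary"
    X_obs, Xs_obs, y_obs, Xs_mis, n_used = _likelihood_inputs(data, spec)
    n_obs, n_mis = X_obs.shape[0], Xs_mis.shape[0]
    if n_obs == 0 or n_mis == 0:
        raise EstimationError(
            "the outcome must have at least one observed and one missing case")
    p, q = X_obs.shape[1], Xs_obs.shape[1]
    d = p + q + (1 if binary else 2)
    if n_used < d:
        raise EstimationError(f"{n_used} usable cases for {d} parameters")

    if binary:
        s = 2.0 * y_obs - 1.0
        objective = lambda th: _binary_nll_grad(th, X_obs, Xs_obs, s, Xs_mis)
    else:
        objective = lambda th: _continuous_nll_grad(th, X_obs, Xs_obs, y_obs, Xs_mis)

    if options.start is not None:
        x0 = np.asarray(options.start, dtype=float)
        if x0.size != d:
            raise ValueError("start vector has the wrong length")
    else:
        x0 = _start_values(X_obs, Xs_obs, y_obs, Xs_mis, binary)

    def _solve(x_init, hess_inv0=None):
        opts = {"maxiter": options.maxiter, "gtol": options.gtol}
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            if options.bound_rho:
                bounds = [(None, None)] * d
                bounds[p + q] = (-options.atanh_rho_cap, options.atanh_rho_cap)
                return optimize.minimize(objective, x_init, jac=True,
                                         method="L-BFGS-B", bounds=bounds,
                                         options={"maxiter": options.maxiter,
                                                  "gtol": options.gtol})
            if hess_inv0 is not None and hess_inv0.shape == (x_init.size, x_init.size):
                # eigen-clip the seed: a near-singular previous psi would give
                # the first quasi-Newton step a catapulting magnitude
                w, V = np.linalg.eigh(0.5 * (hess_inv0 + hess_inv0.T))
                med = max(float(np.median(w)), 1e-12)
                w = np.clip(w, 1e-4 * med, 1e4 * med)
                h0 = (V * w) @ V.T
                # scipy rejects any bitwise-asymmetric seed
                h0 = np.tril(h0) + np.tril(h0, -1).T
                try:
                    return optimize.minimize(objective, x_init, jac=True,
                                             method="BFGS",
                                             options={**opts, "hess_inv0": h0})
                except ValueError:
                    pass  # seed matrix rejected as non-PD; fall through
            return optimize.minimize(objective, x_init, jac=True, method="BFGS",
                                     options=opts)

    res = _solve(x0, options.hess_inv0)
    cap_ok = (abs(res.x[p + q]) <= options.atanh_rho_cap if options.bound_rho
              else abs(res.x[p + q]) < options.atanh_rho_cap)
    ok = res.success and cap_ok
    if not ok and options.retry_on_failure:
        # one deterministic restart from perturbed start values
        perturb = 0.1 * (-1.0) ** np.arange(d) * np.maximum(1.0, np.abs(x0))
        res2 = _solve(x0 + perturb)
        if res2.fun < res.fun or (res2.success and not res.success):
            res = res2
        cap_ok = (abs(res.x[p + q]) <= options.atanh_rho_cap if options.bound_rho
                  else abs(res.x[p + q]) < options.atanh_rho_cap)
        ok = res.success and cap_ok

    theta = res.x
    # BFGS can stop on "precision loss" at a genuine optimum; accept if the
    # gradient is small relative to scale.
    if not ok and not options.bound_rho:
        gnorm = np.max(np.abs(objective(theta)[1]))
        ok = gnorm < 1e-4 * max(1.0, abs(res.fun)) and abs(theta[p + q]) < options.atanh_rho_cap

    psi = None
    if ok:
        if options.vcov == "opg":
            if binary:
                S = _binary_scores(theta, X_obs, Xs_obs, s, Xs_mis)
            else:
                S = _continuous_scores(theta, X_obs, Xs_obs, y_obs, Xs_mis)
            H = S.T @ S
        else:
            H = _fd_hessian(lambda th: objective(th)[1], theta, options.hessian_step)
        try:
            psi = _psd_inverse(H)
        except np.linalg.LinAlgError:
            ok = False
            logger.warning("singular information matrix; fit flagged non-convergent")

    beta, beta_s, rho, sigma = _split_theta(theta, p, q, continuous=not binary)
    params = HeckmanParams(beta=beta, beta_s=beta_s,
                           rho=float(np.clip(rho, -0.99999, 0.99999)),
                           sigma_eps=sigma)
    return HeckmanFit(params=params, theta_uncon=theta, psi=psi,
                      loglik=-res.fun, converged=bool(ok), n_used=n_used,
                      spec=spec, estimator="ml")


# ---------------------------------------------------------------------------
# Two-step (Heckit) estimator — continuous outcomes only
# ---------------------------------------------------------------------------


def fit_heckman_twostep(data: Dataset, spec: HeckmanSpec) -> HeckmanFit:
    """Heckman's two-step estimator for continuous outcomes.

    Step 1 fits a probit of the observedness indicator on the selection
    covariates; step 2 regresses the observed outcomes on the outcome
    covariates plus the inverse Mills ratio ``lambda_i = phi(Xs bs)/Phi(Xs
    bs)``.  ``sigma_eps`` and ``rho`` are recovered from the coefficient on
    ``lambda`` and the step-2 residuals by the standard moment identities.

    The returned ``psi`` is deliberately *uncorrected*: the step-2 covariance
    treats the estimated Mills ratios as known, so first-step uncertainty is
    not propagated — the recognised weakness of the two-step approach relative
    to one-step ML.
    """
    if spec.outcome_kind == "binary":
        raise UnsupportedMethodError(
            "the two-step estimator is not valid for binary outcomes: the "
            "inverse Mills ratio is not an additive correction inside a probit "
            "model; use the one-step maximum-likelihood estimator")
    X_obs, Xs_obs, y_obs, Xs_mis, n_used = _likelihood_inputs(data, spec)
    if X_obs.shape[0] == 0 or Xs_mis.shape[0] == 0:
        raise EstimationError(
            "the outcome must have at least one observed and one missing case")

    n_obs, n_mis = X_obs.shape[0], Xs_mis.shape[0]
    r = np.concatenate([np.ones(n_obs), np.zeros(n_mis)])
    Xs_all = np.vstack([Xs_obs, Xs_mis])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probit = sm.Probit(r, Xs_all).fit(disp=0)
    beta_s = np.asarray(probit.params, dtype=float)
    cov_s = np.asarray(probit.cov_params(), dtype=float)

    bs_lin = Xs_obs @ beta_s
    lam = inverse_mills_ratio(bs_lin)
    delta = lam * (lam + bs_lin)          # Var reduction factor, in (0, 1)
    W = np.column_stack([X_obs, lam])
    ols = sm.OLS(y_obs, W).fit()
    coef = np.asarray(ols.params, dtype=float)
    cov_w = np.asarray(ols.cov_params(), dtype=float)

    def _recover(c):
        beta, blam = c[:-1], c[-1]
        e = y_obs - W @ c
        sig2 = e @ e / n_obs + blam ** 2 * delta.mean()
        sigma = np.sqrt(sig2)
        rho = np.clip(blam / sigma, -0.9999, 0.9999)
        return np.concatenate([beta, [np.arctanh(rho), np.log(sigma)]])

    nat = _recover(coef)
    p = X_obs.shape[1]
    theta = np.concatenate([nat[:p], beta_s, nat[p:]])

    # Delta method: map the step-2 covariance of (beta, beta_lambda) onto
    # (beta, atanh rho, log sigma); beta_s block from the probit, cross zero.
    J = np.empty((p + 2, p + 1))
    for j in range(p + 1):
        h = 1e-6 * max(1.0, abs(coef[j]))
        cp, cm = coef.copy(), coef.copy()
        cp[j] += h
        cm[j] -= h
        J[:, j] = (_recover(cp) - _recover(cm)) / (2.0 * h)
    cov_out = J @ cov_w @ J.T

    d = theta.size
    psi = np.zeros((d, d))
    psi[:p, :p] = cov_out[:p, :p]
    psi[p:p + beta_s.size, p:p + beta_s.size] = cov_s
    psi[:p, p + beta_s.size:] = cov_out[:p, p:]
    psi[p + beta_s.size:, :p] = cov_out[p:, :p]
    psi[p + beta_s.size:, p + beta_s.size:] = cov_out[p:, p:]
    psi = _psd_inverse(_psd_inverse(psi))  # eigen-clip to keep PSD

    rho = float(np.tanh(nat[p]))
    sigma = float(np.exp(nat[p + 1]))
    params = HeckmanParams(beta=nat[:p], beta_s=beta_s, rho=rho, sigma_eps=sigma)
    ll = loglik_continuous(params, data, spec)
    return HeckmanFit(params=params, theta_uncon=theta, psi=psi, loglik=ll,
                      converged=bool(probit.mle_retvals.get("converged", True)),
                      n_used=n_used, spec=spec, estimator="twostep")


# ---------------------------------------------------------------------------
# Plain comparators
# ---------------------------------------------------------------------------


@dataclass
class AnalysisModel:
    """The substantive analysis: probit (binary) or OLS (continuous) of the
    outcome on a covariate list."""

    outcome_var: str
    covars: list[str]
    outcome_kind: str

    def fit(self, values: np.ndarray, names: list[str]) -> pd.DataFrame:
        idx = [names.index(c) for c in self.covars]
        X = np.column_stack([np.ones(values.shape[0])] + [values[:, j] for j in idx])
        y = values[:, names.index(self.outcome_var)]
        if self.outcome_kind == "binary":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Probit(y, X).fit(disp=0)
        else:
            res = sm.OLS(y, X).fit()
        est = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        terms = ["(Intercept)"] + list(self.covars)
        zcrit = 1.959963984540054
        return pd.DataFrame({"term": terms, "estimate": est, "se": se,
                             "z": est / se, "ci_low": est - zcrit * se,
                             "ci_high": est + zcrit * se})


def fit_comparator(data: Dataset, method: str, analysis: AnalysisModel) -> pd.DataFrame:
    """Benchmark fits: ``"before-deletion"`` uses the dataset as given (pass
    the pre-deletion data), ``"cca"`` drops every case with a missing cell
    among the analysis variables."""
    if method not in ("before-deletion", "cca"):
        raise ValueError("method must be 'before-deletion' or 'cca'")
    names = list(data.var_names)
    cols = [analysis.outcome_var] + list(analysis.covars)
    keep = np.ones(data.n_cases, dtype=bool)
    if method == "cca":
        for c in cols:
            keep &= data.observed(c)
    if keep.sum() == 0:
        raise EstimationError("no complete cases for the analysis model")
    return analysis.fit(data.values[keep], names)
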