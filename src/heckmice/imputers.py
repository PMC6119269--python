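"""Proper imputation draws for MNAR outcomes and MAR predictors.

The MNAR imputers are built on a fitted sample-selection model.  For a binary
outcome the probability that a *missing* case is a success differs from the
marginal probit probability:

    P(Y=1 | X, Xs, R=0) = Phi2(X b, -Xs bs, -rho) / Phi(-Xs bs),

and for a continuous outcome the conditional mean of a missing case carries a
selection-correction term:

    E(Y | X, Xs, R=0) = X b + rho * sigma * (-phi(Xs bs)) / Phi(-Xs bs).

Imputation is *proper*: each pass first draws parameters theta* from
N(theta_hat, Psi_hat) on the unconstrained scale (so rho* and sigma* are valid
by construction), then draws outcomes from the conditional model at theta*.
The MAR imputers (Bayesian linear regression and logistic/probit regression
with parameter draws) serve incomplete predictors inside a chained-equations
run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import special
from scipy.stats import norm

from .selection import (Dataset, HeckmanFit, HeckmanParams, HeckmanSpec,
                        EstimationError, _LOG_FLOOR, _split_theta, bvn_cdf)

logger = logging.getLogger("heckmice")

_EXPIT = special.expit


@dataclass
class ImputationMethod:
    """How one incomplete variable is imputed.

    kind: "heckman-binary" | "heckman-continuous" | "mar-linear" | "mar-binary"
    spec: a HeckmanSpec for the heckman kinds; a predictor-name list otherwise.
    link: "logit" | "probit" (mar-binary only).
    estimator: "ml" | "twostep" (heckman-continuous only).
    """

    kind: str
    spec: HeckmanSpec | list[str] | None = None
    link: str = "logit"
    estimator: str = "ml"

    def __post_init__(self) -> None:
        kinds = ("heckman-binary", "heckman-continuous", "mar-linear", "mar-binary")
        if self.kind not in kinds:
            raise ValueError(f"unknown imputation kind {self.kind!r}")
        if self.kind.startswith("heckman") and not isinstance(self.spec, HeckmanSpec):
            raise ValueError("heckman methods require a HeckmanSpec")
        if self.link not in ("logit", "probit"):
            raise ValueError("link must be logit|probit")
        if self.estimator not in ("ml", "twostep"):
            raise ValueError("estimator must be ml|twostep")
        if self.estimator == "twostep" and self.kind == "heckman-binary":
            raise ValueError("the two-step estimator is not valid for binary outcomes")


# String names under which imputers are addressed in config files.
METHOD_ALIASES = {
    "heckman-binary": "heckman-binary",
    "heckman-continuous": "heckman-continuous",
    "norm": "mar-linear",
    "logreg": "mar-binary",
    "probitreg": "mar-binary",
}


@dataclass
class ParamDraw:
    """One draw theta* ~ N(theta_hat, Psi_hat) with its natural-scale image."""

    theta_star: np.ndarray
    natural: HeckmanParams
    draw_index: int = 0


def draw_parameters(fit: HeckmanFit, rng: np.random.Generator,
                    draw_index: int = 0) -> ParamDraw:
    """Draw model parameters from the large-sample posterior N(theta, Psi).

    The draw is made on the unconstrained scale, so the back-transformed
    rho* is always inside (-1, 1) and sigma* is always positive.
    """
    if not fit.converged or fit.psi is None:
        raise EstimationError("refusing to draw parameters from a non-converged fit")
    d = fit.theta_uncon.size
    w, V = np.linalg.eigh(fit.psi)
    root = V * np.sqrt(np.maximum(w, 0.0))
    theta_star = fit.theta_uncon + root @ rng.standard_normal(d)
    p = fit.params.beta.size
    q = fit.params.beta_s.size
    beta, beta_s, rho, sigma = _split_theta(
        theta_star, p, q, continuous=fit.params.sigma_eps is not None)
    natural = HeckmanParams(beta=beta, beta_s=beta_s,
                            rho=float(np.clip(rho, -0.99999, 0.99999)),
                            sigma_eps=sigma)
    return ParamDraw(theta_star=theta_star, natural=natural, draw_index=draw_index)


def mnar_binary_prob(params: HeckmanParams, x: np.ndarray, xs: np.ndarray):
    """P(Y=1 | X, Xs, R=0) under a binary sample-selection model.

    Computed as exp(log Phi2 - log Phi) so that a tiny non-selection
    probability Phi(-Xs bs) does not underflow the ratio.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    a = x @ params.beta
    b = xs @ params.beta_s
    if params.rho == 0.0:
        # MAR reduction: the selection factor cancels exactly
        out = special.ndtr(a)
        return out if out.size > 1 else float(out[0])
    num = np.maximum(bvn_cdf(a, -b, -params.rho), _LOG_FLOOR)
    log_p = np.log(num) - special.log_ndtr(-b)
    out = np.clip(np.exp(log_p), 0.0, 1.0)
    return out if out.size > 1 else float(out[0])


def _mnar_design(fit: HeckmanFit, data: Dataset):
    spec = fit.spec
    miss = ~data.observed(spec.outcome_var)
    X = data.design_matrix(spec.outcome_covars)[miss]
    Xs = data.design_matrix(spec.selection_covars)[miss]
    return miss, X, Xs


def impute_binary_mnar(fit: HeckmanFit, data: Dataset,
                       rng: np.random.Generator) -> np.ndarray:
    """One proper-imputation pass for a binary MNAR outcome.

    A single parameter draw is shared by all missing cases of the pass; each
    case then gets Y* ~ Bernoulli(p*) with p* from the missing-case success
    probability at the drawn parameters.  Returns the imputed values in the
    row order of the missing cases.
    """
    draw = draw_parameters(fit, rng)
    _, X, Xs = _mnar_design(fit, data)
    p_star = np.atleast_1d(mnar_binary_prob(draw.natural, X, Xs))
    return (rng.random(p_star.size) < p_star).astype(float)


def impute_continuous_mnar(fit: HeckmanFit, data: Dataset,
                           rng: np.random.Generator) -> np.ndarray:
    """One proper-imputation pass for a continuous MNAR outcome.

    Y* = X b* + rho* sigma* (-phi(Xs bs*)) / Phi(-Xs bs*) + eps*, with fresh
    eps* ~ N(0, sigma*^2) per case and one parameter draw per pass.
    """
    if fit.params.sigma_eps is None:
        raise ValueError("continuous imputation requires a continuous-outcome fit")
    draw = draw_parameters(fit, rng)
    par = draw.natural
    _, X, Xs = _mnar_design(fit, data)
    b = Xs @ par.beta_s
    # -phi(b)/Phi(-b): the (negative) conditional-mean shift of non-selected
    # cases; evaluated in log space for large b.
    shift = -np.exp(-0.5 * b * b - 0.5 * np.log(2.0 * np.pi) - special.log_ndtr(-b))
    mean = X @ par.beta + par.rho * par.sigma_eps * shift
    return mean + par.sigma_eps * rng.standard_normal(mean.size)


# ---------------------------------------------------------------------------
# MAR imputers for incomplete predictors
# ---------------------------------------------------------------------------


def impute_mar_linear(data: Dataset, target: str, predictors: list[str],
                      rng: np.random.Generator) -> np.ndarray:
    """Proper Bayesian linear-regression imputation of a continuous variable.

    With observed rows (y, X): sigma*^2 = SSE / chi2(n_obs - k) draw, beta* ~
    N(beta_ls, sigma*^2 (X'X)^-1), and imputations x beta* + N(0, sigma*^2)
    for the missing rows — the standard noninformative-prior posterior draw.
    """
    obs = data.observed(target)
    if not obs.any() or obs.all():
        raise EstimationError(f"{target!r} needs both observed and missing cases")
    X = data.design_matrix(predictors)
    for c in predictors:
        if not data.observed(c)[~obs].all() or not data.observed(c)[obs].all():
            raise EstimationError(f"predictor {c!r} must be complete when imputing {target!r}")
    y = data.column(target)
    Xo, yo = X[obs], y[obs]
    n_obs, k = Xo.shape
    if n_obs <= k:
        raise EstimationError("too few observed cases for the linear imputer")
    xtx = Xo.T @ Xo
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        rank = np.linalg.matrix_rank(Xo)
        raise EstimationError(
            f"rank-deficient predictor matrix (rank {rank} < {k}) for {target!r}; "
            f"predictors: {predictors}") from None
    beta_hat = xtx_inv @ (Xo.T @ yo)
    sse = float((yo - Xo @ beta_hat) @ (yo - Xo @ beta_hat))
    sigma2_star = sse / rng.chisquare(n_obs - k)
    L = np.linalg.cholesky(0.5 * (xtx_inv + xtx_inv.T)
                           + 1e-12 * np.eye(k) * max(1.0, np.trace(xtx_inv)))
    beta_star = beta_hat + np.sqrt(sigma2_star) * (L @ rng.standard_normal(k))
    Xm = X[~obs]
    return Xm @ beta_star + np.sqrt(sigma2_star) * rng.standard_normal(Xm.shape[0])


def _firth_logit(y, X, max_iter=50, tol=1e-8):
    """Jeffreys-prior (Firth) penalised logistic fit, used as the fallback
    when the plain ML fit separates."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = _EXPIT(eta)
        w = mu * (1.0 - mu)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta, info_inv


def impute_mar_binary(data: Dataset, target: str, predictors: list[str],
                      link: str, rng: np.random.Generator) -> np.ndarray:
    """Proper imputation of a binary variable by logistic or probit regression
    with a normal parameter draw; falls back to a Jeffreys-penalised logistic
    fit under complete separation."""
    if link not in ("logit", "probit"):
        raise ValueError("link must be logit|probit")
    obs = data.observed(target)
    if not obs.any() or obs.all():
        raise EstimationError(f"{target!r} needs both observed and missing cases")
    X = data.design_matrix(predictors)
    y = data.column(target)
    Xo, yo = X[obs], y[obs]

    model = sm.Logit(yo, Xo) if link == "logit" else sm.Probit(yo, Xo)
    beta_hat, cov = None, None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=100)
        beta_hat = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        if not (np.all(np.isfinite(beta_hat)) and np.all(np.isfinite(cov))
                and np.max(np.abs(beta_hat)) < 50.0
                and np.max(np.diag(cov)) < 1e4):
            beta_hat = None  # runaway coefficients: (quasi-)separation
    except Exception:
        beta_hat = None
    if beta_hat is None:
        logger.warning("separation detected imputing %r; using a Jeffreys-"
                       "penalised logistic fit", target)
        beta_hat, cov = _firth_logit(yo, Xo)
        link = "logit"

    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    beta_star = beta_hat + (V * np.sqrt(np.maximum(w, 0.0))) @ rng.standard_normal(len(beta_hat))
    eta = X[~obs] @ beta_star
    p = _EXPIT(eta) if link == "logit" else norm.cdf(eta)
    return (rng.random(p.size) < p).astype(float)
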