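"""Multiple imputation by chained equations with sample-selection imputers.

The engine iterates variable-by-variable conditional imputation: after an
initial fill by resampling observed values, each cycle re-estimates every
incomplete variable's conditional model on the currently-completed data and
overwrites that variable's originally-missing cells with fresh proper
imputations.  MNAR outcomes use the Heckman imputers, whose selection
response is always the *original* missingness indicator; MAR predictors use
Bayesian linear or logistic/probit imputers whose models are automatically
augmented with the MNAR outcome and its missingness indicator.  Running m
independent chains yields m completed datasets, combined by Rubin's rules
with Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .imputers import (ImputationMethod, impute_binary_mnar,
                       impute_continuous_mnar, impute_mar_binary,
                       impute_mar_linear)
from .selection import (AnalysisModel, Dataset, EstimationError, FitOptions,
                        HeckmanSpec, fit_heckman_ml, fit_heckman_twostep)

logger = logging.getLogger("heckmice")


class ChainError(RuntimeError):
    """A chain aborted (persistent non-convergence of a conditional model)."""


class ConfigError(ValueError):
    """Invalid chained-equations configuration."""


@dataclass
class ChainConfig:
    """Configuration of one chained-equations run."""

    methods: dict[str, ImputationMethod]
    m: int = 5
    iterations: int = 20
    seed: int = 0
    visit_order: list[str] | None = None
    strict: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")

    def validated_order(self, data: Dataset) -> list[str]:
        incomplete = [v for v in data.var_names if not data.is_complete(v)]
        for v in incomplete:
            if v not in self.methods:
                raise ConfigError(f"incomplete variable {v!r} has no imputation method")
        for v in self.methods:
            if v not in data.var_names:
                raise ConfigError(f"method assigned to unknown variable {v!r}")
            if data.is_complete(v):
                raise ConfigError(f"method assigned to complete variable {v!r}")
        order = self.visit_order or incomplete
        if sorted(order) != sorted(incomplete):
            raise ConfigError("visit_order must list exactly the incomplete variables")
        return order


@dataclass
class ImputedSet:
    """m completed copies of a dataset plus provenance."""

    completed: list[Dataset]
    indicator_vars: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.completed)

    def stacked(self) -> pd.DataFrame:
        """Long-format stack of the completed copies with an `_imp` index."""
        frames = []
        for i, ds in enumerate(self.completed, start=1):
            df = ds.to_dataframe()
            df.insert(0, "_imp", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass
class PooledEstimate:
    """Rubin-combined estimates across m imputed datasets."""

    qbar: np.ndarray
    W: np.ndarray
    B: np.ndarray
    T: np.ndarray
    df: np.ndarray
    ci95: np.ndarray  # (p, 2)
    m: int


# ---------------------------------------------------------------------------
# Chained equations
# ---------------------------------------------------------------------------


def initial_fill(data: Dataset, rng: np.random.Generator) -> Dataset:
    """Replace every missing cell by a uniform draw from that variable's
    observed values; observed cells are untouched."""
    out = data.copy()
    for j, name in enumerate(data.var_names):
        mask = data.obs_mask[:, j]
        if mask.all():
            continue
        obs_vals = data.values[mask, j]
        if obs_vals.size == 0:
            raise ConfigError(f"variable {name!r} has no observed values to fill from")
        out.values[~mask, j] = rng.choice(obs_vals, size=int((~mask).sum()), replace=True)
    return out


def _augmented(data: Dataset, methods: dict[str, ImputationMethod]):
    """Append permanent R indicator columns for Heckman-imputed variables."""
    indicators: dict[str, np.ndarray] = {}
    aug = data.copy()
    for var, meth in methods.items():
        if meth.kind.startswith("heckman"):
            r = data.observed(var).astype(float)
            name = f"R_{var}"
            if name in aug.var_names:
                continue
            aug.values = np.column_stack([aug.values, r])
            aug.obs_mask = np.column_stack([aug.obs_mask, np.ones(len(r), dtype=bool)])
            aug.var_names.append(name)
            aug.var_kinds[name] = "binary"
            indicators[name] = r
    return aug, indicators


def _mar_predictors(target: str, data: Dataset,
                    methods: dict[str, ImputationMethod],
                    given: list[str] | None) -> list[str]:
    """Predictor set for a MAR imputer: the configured list (default: all
    other variables) augmented with each MNAR outcome and its R indicator."""
    if given is None:
        preds = [v for v in data.var_names if v != target]
    else:
        preds = [p for p in given if p != target]
        for var, meth in methods.items():
            if meth.kind.startswith("heckman") and var != target:
                if var not in preds:
                    preds.append(var)
                rname = f"R_{var}"
                if rname in data.var_names and rname not in preds:
                    preds.append(rname)
    return preds


def run_chain(data: Dataset, cfg: ChainConfig, rng: np.random.Generator,
              _order: list[str] | None = None,
              _warm: dict | None = None) -> tuple[Dataset, dict]:
    """One chained-equations pass producing a single completed dataset.

    Returns the completed dataset (with appended indicator columns) and a
    provenance dict with the per-iteration mean trace of each imputed
    variable.  Heckman conditional models are re-fit each visit using the
    original missingness indicator as the selection response; only
    originally-missing cells are ever overwritten.
    """
    order = _order if _order is not None else cfg.validated_order(data)
    if not order:
        return data.copy(), {"trace": {}, "fits": 0}

    aug, _ = _augmented(data, cfg.methods)
    orig_mask = {v: data.observed(v).copy() for v in order}
    work = initial_fill(aug, rng)
    work.obs_mask = np.ones_like(work.obs_mask)  # work holds completed values

    warm: dict[str, tuple[np.ndarray, np.ndarray | None]] = (
        _warm if _warm is not None else {})
    trace: dict[str, list[float]] = {v: [] for v in order}
    n_fits = 0

    for it in range(cfg.iterations):
        for var in order:
            meth = cfg.methods[var]
            j = work.index(var)
            miss = ~orig_mask[var]
            if meth.kind.startswith("heckman"):
                view = work.copy()
                view.obs_mask[:, j] = orig_mask[var]
                view.values[miss, j] = np.nan
                fit = _fit_heckman_visit(view, meth, warm.get(var))
                if fit is None:
                    raise ChainError(
                        f"Heckman fit for {var!r} failed to converge at "
                        f"iteration {it + 1}")
                warm[var] = (fit.theta_uncon, fit.psi)
                if meth.kind == "heckman-binary":
                    imputed = impute_binary_mnar(fit, view, rng)
                else:
                    imputed = impute_continuous_mnar(fit, view, rng)
            else:
                preds = _mar_predictors(var, work,
                                        cfg.methods,
                                        meth.spec if isinstance(meth.spec, list) else None)
                view = work.copy()
                view.obs_mask[:, j] = orig_mask[var]
                if meth.kind == "mar-linear":
                    imputed = impute_mar_linear(view, var, preds, rng)
                else:
                    imputed = impute_mar_binary(view, var, preds, meth.link, rng)
            n_fits += 1
            work.values[miss, j] = imputed
            trace[var].append(float(np.mean(imputed)))

    completed = work
    completed.obs_mask = np.ones_like(completed.obs_mask)
    return completed, {"trace": trace, "fits": n_fits}


def _fit_heckman_visit(view: Dataset, meth: ImputationMethod,
                       warm: tuple[np.ndarray, np.ndarray | None] | None):
    """Fit the Heckman conditional model for one visit, retrying from cold
    start values if the warm-started fit does not converge."""
    spec: HeckmanSpec = meth.spec
    if meth.kind == "heckman-continuous" and meth.estimator == "twostep":
        try:
            fit = fit_heckman_twostep(view, spec)
            return fit if fit.converged else None
        except EstimationError:
            return None
    # Warm-started fit, then a cold restart, then a cold fit with atanh(rho)
    # bounded at the cap: the correlation MLE can genuinely sit on the
    # |rho| -> 1 boundary for some chain states, and the bounded fit imputes
    # from the constrained optimum instead of aborting the chain.
    # OPG (BHHH) information inside the chain: one vectorised evaluation
    # instead of a finite-difference Hessian per visit
    attempts = ([] if warm is None
                else [FitOptions(start=warm[0], hess_inv0=warm[1], vcov="opg")])
    attempts += [FitOptions(vcov="opg"), FitOptions(bound_rho=True, vcov="opg")]
    for opts in attempts:
        try:
            fit = fit_heckman_ml(view, spec, opts)
        except EstimationError:
            return None
        if fit.converged:
            return fit
    return None


def multiple_impute(data: Dataset, cfg: ChainConfig) -> ImputedSet:
    """Run m independent chains (one RNG substream each, derived from
    cfg.seed) and collect the completed datasets."""
    order = cfg.validated_order(data)
    aug, indicators = _augmented(data, cfg.methods)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.m)
    warm_shared: dict = {}  # optimiser warm starts carried across chains
    completed: list[Dataset] = []
    traces = []
    failures = 0
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            ds, prov = run_chain(data, cfg, rng, _order=order, _warm=warm_shared)
        except ChainError as exc:
            failures += 1
            logger.warning("chain %d aborted: %s", i + 1, exc)
            if cfg.strict:
                raise
            continue
        completed.append(ds)
        traces.append(prov["trace"])
    if not completed:
        raise ChainError("all chains aborted")
    if failures:
        logger.warning("%d of %d chains aborted; returning %d completed datasets",
                       failures, cfg.m, len(completed))
    provenance = {
        "seed": cfg.seed,
        "iterations": cfg.iterations,
        "methods": {v: m.kind for v, m in cfg.methods.items()},
        "traces": traces,
        "aborted_chains": failures,
    }
    return ImputedSet(completed=completed, indicator_vars=indicators,
                      provenance=provenance)


# ---------------------------------------------------------------------------
# Rubin's rules (small-sample pooling)
# ---------------------------------------------------------------------------


def pool_rubin(estimates: np.ndarray, variances: np.ndarray,
               n_com_df: float) -> PooledEstimate:
    """Combine m per-imputation estimates and squared SEs.

    qbar is the mean estimate, W the mean within-imputation variance, B the
    between-imputation variance, T = W + (1 + 1/m) B.  Degrees of freedom
    follow Barnard & Rubin's small-sample adjustment:

        nu_old = (m - 1) (1 + W / ((1 + 1/m) B))^2
        nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - gamma)
        gamma  = (1 + 1/m) B / T
        nu_adj = (1/nu_old + 1/nu_obs)^-1

    With B = 0 (no between-imputation variability) df falls back to nu_com.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    var = np.atleast_2d(np.asarray(variances, dtype=float))
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have matching shapes")
    m = est.shape[0]
    if m < 1:
        raise ValueError("need at least one imputation")
    qbar = est.mean(axis=0)
    W = var.mean(axis=0)
    B = est.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    T = W + (1.0 + 1.0 / m) * B

    df = np.empty_like(qbar)
    nu_com = float(n_com_df)
    for j in range(qbar.size):
        if B[j] <= 0 or m < 2:
            df[j] = nu_com
            continue
        gamma = (1.0 + 1.0 / m) * B[j] / T[j]
        nu_old = (m - 1) * (1.0 + W[j] / ((1.0 + 1.0 / m) * B[j])) ** 2
        nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - gamma)
        df[j] = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    tq = t_dist.ppf(0.975, df)
    half = tq * np.sqrt(T)
    ci95 = np.column_stack([qbar - half, qbar + half])
    return PooledEstimate(qbar=qbar, W=W, B=B, T=T, df=df, ci95=ci95, m=m)


def pool_analysis(imputed: ImputedSet, analysis: AnalysisModel,
                  n_com_df: float | None = None) -> pd.DataFrame:
    """Fit the analysis model on each completed dataset and pool the
    coefficients with Rubin's small-sample rules."""
    ests, varis = [], []
    terms = None
    for ds in imputed.completed:
        tab = analysis.fit(ds.values, ds.var_names)
        terms = list(tab["term"])
        ests.append(tab["estimate"].to_numpy())
        varis.append(tab["se"].to_numpy() ** 2)
    n = imputed.completed[0].n_cases
    if n_com_df is None:
        n_com_df = n - len(terms)
    pooled = pool_rubin(np.array(ests), np.array(varis), n_com_df)
    return pd.DataFrame({
        "term": terms,
        "estimate": pooled.qbar,
        "se": np.sqrt(pooled.T),
        "df": pooled.df,
        "ci_low": pooled.ci95[:, 0],
        "ci_high": pooled.ci95[:, 1],
    })
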