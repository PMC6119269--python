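"""CSV readers/writers, config parsing and fixture generation.

Data travel as plain CSV (header row required; empty cells or "NA" mark
missing values).  Chained-equations runs are described by a small YAML config
with one block per incomplete variable naming its imputation method and, for
the selection-model methods, the outcome- and selection-equation covariates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .imputers import METHOD_ALIASES, ImputationMethod
from .mice import ChainConfig, ImputedSet
from .selection import Dataset, HeckmanSpec

logger = logging.getLogger("heckmice")

NA_STRINGS = ["", "NA"]


class ParseError(ValueError):
    """Malformed input data or config file."""


def read_dataset(path, schema: dict[str, str] | None = None) -> Dataset:
    """Read a CSV table into a Dataset.

    Variable kinds are inferred (observed values all in {0,1} -> binary)
    unless overridden through ``schema`` (name -> "binary"|"continuous").
    Non-numeric cells raise a ParseError naming the row and column.
    """
    try:
        df = pd.read_csv(path, na_values=NA_STRINGS, keep_default_na=False,
                         skipinitialspace=True, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    num = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {df[col][row]!r} at row {row + 2}, "
                f"column {col!r}")
        num[col] = converted
    return Dataset.from_dataframe(num, var_kinds=schema)


def write_dataset(data: Dataset, path) -> None:
    data.to_dataframe().to_csv(path, index=False, na_rep="NA")


def write_imputed_set(imputed: ImputedSet, prefix) -> list[Path]:
    """Write m completed CSVs (``<prefix>_imp<i>.csv``) plus a long-format
    stacked CSV (``<prefix>_stacked.csv``)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, ds in enumerate(imputed.completed, start=1):
        p = prefix.parent / f"{prefix.name}_imp{i}.csv"
        write_dataset(ds, p)
        paths.append(p)
    stacked = prefix.parent / f"{prefix.name}_stacked.csv"
    imputed.stacked().to_csv(stacked, index=False)
    paths.append(stacked)
    return paths


# ---------------------------------------------------------------------------
# Chain config files
# ---------------------------------------------------------------------------


def parse_chain_config(path, data: Dataset, m: int | None = None,
                       iterations: int | None = None,
                       seed: int | None = None) -> tuple[ChainConfig, dict | None]:
    """Read a YAML chained-equations config.

    Layout::

        version: 1
        m: 50
        iterations: 20
        seed: 7
        variables:
          Y:
            method: heckman-binary        # or heckman-continuous|norm|logreg|probitreg
            outcome_covars: [X1, X2]      # heckman methods
            selection_covars: [X1, X2, X3]
            estimator: ml                 # heckman-continuous: ml|twostep
          X2:
            method: norm
            predictors: [X1, X3]          # optional; default all other variables
        analysis:                         # optional pooled analysis
          outcome: Y
          covars: [X1, X2]

    Command-line ``m``/``iterations``/``seed`` override the file.
    Returns (ChainConfig, analysis block or None).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "variables" not in raw:
        raise ParseError(f"{path}: config must be a mapping with a 'variables' block")
    if raw.get("version", 1) != 1:
        raise ParseError(f"{path}: unsupported config version {raw.get('version')!r}")
    methods: dict[str, ImputationMethod] = {}
    for var, block in raw["variables"].items():
        if not isinstance(block, dict) or "method" not in block:
            raise ParseError(f"{path}: variable {var!r} needs a 'method' entry")
        name = block["method"]
        if name not in METHOD_ALIASES:
            raise ParseError(f"{path}: unknown method {name!r} for {var!r} "
                             f"(known: {sorted(METHOD_ALIASES)})")
        kind = METHOD_ALIASES[name]
        if kind.startswith("heckman"):
            spec = HeckmanSpec(
                outcome_var=var,
                outcome_covars=list(block.get("outcome_covars", [])),
                selection_covars=list(block.get("selection_covars", [])),
                outcome_kind="binary" if kind == "heckman-binary" else "continuous",
            )
            methods[var] = ImputationMethod(
                kind=kind, spec=spec, estimator=block.get("estimator", "ml"))
        else:
            preds = block.get("predictors")
            link = "probit" if name == "probitreg" else block.get("link", "logit")
            methods[var] = ImputationMethod(
                kind=kind, spec=list(preds) if preds else None, link=link)
    cfg = ChainConfig(
        methods=methods,
        m=m if m is not None else int(raw.get("m", 5)),
        iterations=iterations if iterations is not None else int(raw.get("iterations", 20)),
        seed=seed if seed is not None else int(raw.get("seed", 0)),
        visit_order=raw.get("visit_order"),
    )
    cfg.validated_order(data)
    return cfg, raw.get("analysis")


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

FIXTURE_TAGS = {
    "binary-rho0": dict(outcome_kind="binary", mechanism="heckman", rho=0.0),
    "binary-rho03": dict(outcome_kind="binary", mechanism="heckman", rho=0.3),
    "binary-rho06": dict(outcome_kind="binary", mechanism="heckman", rho=0.6),
    "continuous-rho0": dict(outcome_kind="continuous", mechanism="heckman", rho=0.0),
    "continuous-rho06": dict(outcome_kind="continuous", mechanism="heckman", rho=0.6),
    "binary-logit2": dict(outcome_kind="binary", mechanism="logit_y", beta_y_sl=2.0),
    "binary-rho06-x2A": dict(outcome_kind="binary", mechanism="heckman", rho=0.6,
                             x2_missing="mech_A"),
    "continuous-rho06-x2B": dict(outcome_kind="continuous", mechanism="heckman",
                                 rho=0.6, x2_missing="mech_B"),
}


def make_fixture(name: str, seed: int, out_dir, n: int = 200) -> list[Path]:
    """Write a small deterministic replicate of one study scenario:
    ``<name>.csv`` (post-deletion) and ``<name>_full.csv`` (pre-deletion)."""
    from .simulate import ScenarioConfig, generate_replicate

    if name not in FIXTURE_TAGS:
        raise ParseError(f"unknown fixture tag {name!r} (known: {sorted(FIXTURE_TAGS)})")
    cfg = ScenarioConfig(n=n, reps=1, seed=seed, **FIXTURE_TAGS[name])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sim = generate_replicate(cfg, rng)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p_obs = out_dir / f"{name}.csv"
    p_full = out_dir / f"{name}_full.csv"
    write_dataset(sim.observed, p_obs)
    write_dataset(sim.full, p_full)
    return [p_obs, p_full]
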