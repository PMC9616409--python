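"""CSV/JSON input-output and the end-to-end pipeline.

The pipeline reproduces the optimization workflow stage by stage:
screen (first-order fit of the Plackett-Burman table + effect selection),
fit (full quadratic response surface), optimize (desirability maximization
over a coded box) and validate (percent error of a confirmation run).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .designs import DesignMatrix
from .errors import SchemaError
from .factors import FactorDefinition, load_factor_definitions
from .optimize import DesirabilityGoal, maximize_surface, validation_error
from .surface import ExperimentTable, anova, fit_least_squares, screen_effects

__all__ = ["load_experiment_csv", "write_report", "fit_report",
           "PipelineConfig", "run_pipeline"]

log = logging.getLogger("fermopt")


def load_experiment_csv(path: str | Path, design_type: str = "central_composite",
                        n_center: int | None = None, alpha: float | None = None
                        ) -> ExperimentTable:
    """Read an experiment CSV with columns ``run,<factor...>,response``.

    A ``predicted`` column, if present, is ignored as metadata.  Malformed
    rows are reported with their line numbers; duplicate run ids and
    non-numeric cells are schema errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in ("run", "response"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df["run"].duplicated().any():
        dupes = df.loc[df["run"].duplicated(), "run"].tolist()
        raise SchemaError(f"{path}: duplicate run ids {dupes}")
    factors = [c for c in df.columns if c not in ("run", "response", "predicted")]
    if not factors:
        raise SchemaError(f"{path}: no factor columns found")
    bad_lines = []
    for col in factors + ["response"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        for pos in np.nonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())[0]:
            bad_lines.append((int(pos) + 2, col, df[col].iloc[pos]))
        df[col] = coerced
    if bad_lines:
        detail = "; ".join(f"line {ln}: column {c!r} value {v!r}" for ln, c, v in bad_lines)
        raise SchemaError(f"{path}: non-numeric cells ({detail})")
    if df[factors + ["response"]].isna().any().any():
        raise SchemaError(f"{path}: missing values in factor/response columns")
    rows = df[factors].set_axis(pd.Index(df["run"].astype(int), name="run"))
    meta: dict[str, Any] = {}
    if design_type == "central_composite":
        X = rows.to_numpy(float)
        meta["n_center"] = int(n_center if n_center is not None
                               else (X == 0).all(axis=1).sum())
        meta["alpha"] = float(alpha if alpha is not None
                              else max(np.abs(X).max(), 1.0))
    design = DesignMatrix(design_type=design_type, rows=rows, **meta)
    return ExperimentTable(design=design, response=df["response"])


def fit_report(model) -> dict:
    """JSON-ready summary of a fitted surface: coefficients, R^2 family,
    ANOVA rows and the per-run observed/fitted/residual/leverage table."""
    return {
        "coefficients": {k: float(v) for k, v in model.coefficients_.items()},
        "factor_names": list(model.factor_names_),
        "n": model.n_, "p": model.p_,
        "r2": model.r2_, "r2_adjusted": model.r2_adjusted_,
        "r2_predicted": model.r2_predicted_,
        "sse": model.sse_, "sst": model.sst_, "press": model.press_,
        "anova": anova(model).reset_index().to_dict(orient="records"),
        "per_run": model.summary_frame().to_dict(orient="list"),
    }


def write_report(report: dict, path: str | Path) -> None:
    """Write any stage report as indented JSON (UTF-8, '.' decimals)."""
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


class PipelineConfig(BaseModel):
    """Validated configuration of the end-to-end pipeline."""

    model_config = ConfigDict(extra="forbid")

    screen_table: str | None = None
    rsm_table: str | None = None
    factor_config: str | None = None
    significance_level: float = Field(default=0.05, gt=0, lt=1)
    region: str = "unit-cube"  # or "design-cube"
    desirability_lower: float | None = None
    desirability_upper: float | None = None
    desirability_weight: float = Field(default=1.0, gt=0)
    grid_resolution: float = Field(default=0.01, gt=0)
    validation_actual: float | None = None
    seed: int = 0
    output_dir: str = "."
    verbosity: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run screen -> fit -> optimize -> validate and return one JSON report.

    Each stage logs its parameters; a failure aborts with the stage name.
    Per-stage CSVs and the report are written under ``config.output_dir``.
    """
    logging.basicConfig(level=config.verbosity)
    from . import datasets  # local import to keep module load light

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    stage = "resolve-inputs"
    try:
        if config.screen_table:
            screen_tab = load_experiment_csv(config.screen_table,
                                             design_type="plackett_burman")
        else:
            screen_tab, _ = datasets.load_pbd_screen(reconciled=True)
        if config.rsm_table:
            rsm_tab = load_experiment_csv(config.rsm_table)
        else:
            rsm_tab, _ = datasets.load_rsm_experiment()
        factors = (load_factor_definitions(config.factor_config)
                   if config.factor_config else datasets.load_rsm_factors())

        stage = "screen"
        log.info("screen: first-order fit, alpha=%g", config.significance_level)
        screen_fit = fit_least_squares(screen_tab, "first-order")
        effects = screen_effects(screen_fit, config.significance_level)
        effects.to_csv(out_dir / "screen_effects.csv")
        report["stages"]["screen"] = {
            "coefficients": screen_fit.coefficients_,
            "retained_factors": effects.index[effects["keep"]].tolist(),
            "r2": screen_fit.r2_,
        }

        stage = "fit"
        log.info("fit: full quadratic response surface")
        rsm_fit = fit_least_squares(rsm_tab, "quadratic")
        rsm_fit.summary_frame().to_csv(out_dir / "rsm_fit_per_run.csv")
        report["stages"]["fit"] = fit_report(rsm_fit)

        stage = "optimize"
        k = rsm_fit.n_features_in_
        half = 1.0 if config.region == "unit-cube" else (rsm_tab.design.alpha or 1.0)
        region = [(-half, half)] * k
        goal = None
        if config.desirability_lower is not None and config.desirability_upper is not None:
            goal = DesirabilityGoal(config.desirability_lower,
                                    config.desirability_upper,
                                    config.desirability_weight)
        log.info("optimize: region=%s resolution=%g", config.region,
                 config.grid_resolution)
        opt = maximize_surface(rsm_fit, region=region, goal=goal,
                               resolution=config.grid_resolution, factors=factors)
        report["stages"]["optimize"] = opt.to_dict()

        stage = "validate"
        if config.validation_actual is not None:
            err = validation_error(config.validation_actual, opt.predicted_response)
            report["stages"]["validate"] = {
                "actual": config.validation_actual,
                "predicted": opt.predicted_response,
                "percent_error": err,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_report(report, out_dir / "pipeline_report.json")
    return report
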