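"""Bundled experiment fixtures: the published screening and response-surface
tables, factor-level mappings, and a synthetic microdilution plate set.

All loaders return ready-to-use package objects; the published ``predicted``
columns are returned alongside so fits can be checked against them.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .bioassay import PlateGrowthMatrix
from .designs import DesignMatrix
from .factors import FactorDefinition, load_factor_definitions
from .surface import ExperimentTable

__all__ = [
    "load_pbd_screen",
    "load_rsm_experiment",
    "load_pbd_factors",
    "load_rsm_factors",
    "load_mic_plates",
]

_DATA = resources.files("fermopt") / "data"


def _read(name: str) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        return pd.read_csv(fh, comment="#")


def _split(df: pd.DataFrame, design_type: str, **meta):
    levels = df.drop(columns=["run", "response", "predicted"])
    rows = levels.set_axis(pd.Index(df["run"].astype(int), name="run"))
    design = DesignMatrix(design_type=design_type, rows=rows, **meta)
    table = ExperimentTable(design=design, response=df["response"])
    predicted = pd.Series(df["predicted"].to_numpy(), index=rows.index,
                          name="predicted")
    return table, predicted


def load_pbd_screen(reconciled: bool = True) -> tuple[ExperimentTable, pd.Series]:
    """The 12-run, 11-factor Plackett-Burman screen of carotenoid yield.

    With ``reconciled=True`` (default) run 12's observed yield is the
    value consistent with the published first-order fit (58.952 ug/ml);
    ``reconciled=False`` returns the observations exactly as published,
    whose run 12 (158.900) is internally inconsistent with the published
    predicted column (see docs/methods.md).
    """
    name = "pbd_screen_reconciled.csv" if reconciled else "pbd_screen_as_printed.csv"
    return _split(_read(name), "plackett_burman")


def load_rsm_experiment() -> tuple[ExperimentTable, pd.Series]:
    """The 30-run central composite inscribed experiment (4 factors, alpha=2,
    6 centre runs) with observed carotenoid yields."""
    return _split(_read("rsm_design.csv"), "central_composite",
                  n_center=6, alpha=2.0)


def _factors(name: str) -> list[FactorDefinition]:
    with resources.as_file(_DATA / name) as path:
        return load_factor_definitions(path)


def load_pbd_factors() -> list[FactorDefinition]:
    """Level mappings (low/high actual units) of the 11 screened factors."""
    return _factors("pbd_factor_levels.json")


def load_rsm_factors() -> list[FactorDefinition]:
    """Five-level mappings of the 4 response-surface factors."""
    return _factors("rsm_factor_levels.json")


def load_mic_plates() -> list[PlateGrowthMatrix]:
    """Synthetic broth-microdilution growth flags for six pathogens.

    Only MIC/MBC endpoints were published; the well-by-well flags are the
    unique monotone reconstruction consistent with them (file is labelled
    synthetic accordingly).
    """
    df = _read("mic_mbc_plates_synthetic.csv")
    plates = []
    for pathogen, grp in df.groupby("pathogen", sort=False):
        grp = grp.sort_values("concentration")
        plates.append(PlateGrowthMatrix(
            pathogen=str(pathogen),
            concentrations=grp["concentration"].to_numpy(float),
            broth_growth=grp["broth_growth"].to_numpy(bool),
            subculture_growth=grp["subculture_growth"].to_numpy(bool)))
    return plates


def published_screen_coefficients() -> dict[str, float]:
    """Published first-order screening model (intercept + 4 significant factors)."""
    return {"Intercept": 186.62, "peptone": 29.81, "temperature": -85.54,
            "agitation": 68.92, "inoculum_size": 37.03}


def published_quadratic_coefficients() -> dict[str, float]:
    """Published full quadratic response-surface model over the 4 factors
    A=peptone, B=temperature, C=agitation, D=inoculum size."""
    return {
        "Intercept": 509.25,
        "peptone": 48.81, "temperature": -176.76, "agitation": 75.91,
        "inoculum_size": -23.59,
        "peptone:temperature": -24.93, "peptone:agitation": 26.80,
        "peptone:inoculum_size": 31.39, "temperature:agitation": -30.63,
        "temperature:inoculum_size": 3.76, "agitation:inoculum_size": 0.32,
        "peptone^2": -43.09, "temperature^2": -16.06,
        "agitation^2": 28.01, "inoculum_size^2": 19.93,
    }
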