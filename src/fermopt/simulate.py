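"""Synthetic data generators mirroring the structure of the real experiments.

Two generators cover the two analysis stages:

* :func:`simulate_surface` draws responses from a known polynomial on a
  coded design plus i.i.d. Gaussian noise (floored at zero, since yields
  are concentrations);
* :func:`simulate_dose_response` draws replicate percent responses around
  a four-parameter logistic forward curve, clipped to [bottom, top].

Both are driven by numpy's seeded PCG64 generator.  A scenario's ``seed``
is expanded through ``SeedSequence`` substreams keyed by the scenario kind,
so adding one scenario never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioassay import DoseResponseCurve, _fourpl
from .designs import DesignMatrix
from .surface import ExperimentTable, ModelSpec, build_model_matrix

__all__ = ["SurfaceScenario", "CurveScenario", "simulate_surface",
           "simulate_dose_response"]

_STREAM = {"surface": 0, "curve": 1}


def _rng(seed: int, kind: str) -> np.random.Generator:
    root = np.random.SeedSequence(seed)
    return np.random.default_rng(root.spawn(len(_STREAM))[_STREAM[kind]])


@dataclass
class SurfaceScenario:
    """Known polynomial truth on a coded design, with Gaussian noise."""

    design: DesignMatrix
    spec: ModelSpec
    true_coefficients: np.ndarray  # aligned with spec.terms
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_coefficients = np.asarray(self.true_coefficients, dtype=float)
        if len(self.true_coefficients) != self.spec.n_terms:
            raise ValueError("true_coefficients must match the term count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class CurveScenario:
    """Four-parameter logistic truth sampled on a dose grid with replicates."""

    ic50: float
    doses: np.ndarray
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    n_replicates: int = 3
    noise_sd: float = 0.0
    seed: int = 0
    response_kind: str = "inhibition"

    def __post_init__(self) -> None:
        self.doses = np.sort(np.asarray(self.doses, dtype=float))
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if not self.top > self.bottom:
            raise ValueError("top must exceed bottom")
        if self.noise_sd < 0 or self.n_replicates < 1:
            raise ValueError("invalid noise_sd or replicate count")


def simulate_surface(scenario: SurfaceScenario) -> ExperimentTable:
    """Draw one response per design run from the scenario's polynomial truth."""
    M = build_model_matrix(scenario.design, scenario.spec).to_numpy()
    mean = M @ scenario.true_coefficients
    rng = _rng(scenario.seed, "surface")
    noise = rng.normal(0.0, scenario.noise_sd, size=len(mean)) if scenario.noise_sd else 0.0
    y = np.maximum(mean + noise, 0.0)  # yields are concentrations
    return ExperimentTable(design=scenario.design,
                           response=pd.Series(y, index=scenario.design.rows.index))


def simulate_dose_response(scenario: CurveScenario) -> DoseResponseCurve:
    """Draw a replicate-averaged dose-response curve from a 4PL truth.

    The 4PL midpoint is placed at the scenario IC50 (with symmetric
    bottom/top defaults the midpoint is exactly the 50 % crossing); a
    negative ``hill`` or ``response_kind="viability"`` yields a falling
    curve.
    """
    logc = np.log10(scenario.doses)
    hill = scenario.hill
    if scenario.response_kind == "viability" and hill > 0:
        hill = -hill
    mean = _fourpl(logc, scenario.bottom, scenario.top, np.log10(scenario.ic50), hill)
    rng = _rng(scenario.seed, "curve")
    shape = (len(mean), scenario.n_replicates)
    noise = (rng.normal(0.0, scenario.noise_sd, size=shape)
             if scenario.noise_sd else np.zeros(shape))
    reps = np.clip(mean[:, None] + noise, scenario.bottom, scenario.top)
    sd = reps.std(axis=1, ddof=1) if scenario.n_replicates > 1 else np.zeros(len(mean))
    return DoseResponseCurve(concentrations=scenario.doses,
                             responses=reps.mean(axis=1),
                             sd=sd, response_kind=scenario.response_kind)
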