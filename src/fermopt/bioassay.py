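"""In vitro assay analytics: percent formulas, dose-response curves, MIC/MBC.

Covers the standard readouts of an extract-characterization screen:

* thin-layer chromatography retention factor;
* erythrocyte membrane-stabilization (hemolysis inhibition) percent;
* generic percent inhibition (DPPH radical scavenging, alpha-glucosidase);
* scratch-assay wound closure percent (areas as numeric inputs);
* IC50 from a four-parameter logistic (4PL) dose-response fit;
* maximum non-toxic dose (MNTD) from a viability curve;
* selectivity index (normal-cell IC50 / cancer-cell IC50);
* MIC/MBC reduction of broth-microdilution plate growth flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import NoNonToxicDoseError, NotEstimableError

__all__ = [
    "retention_factor",
    "hemolysis_inhibition",
    "percent_inhibition",
    "wound_closure",
    "DoseResponseCurve",
    "FourParamLogistic",
    "estimate_ic50",
    "mntd",
    "selectivity_index",
    "PlateGrowthMatrix",
    "MicMbcResult",
    "mic_mbc",
]


# ---------------------------------------------------------------------------
# closed-form percent metrics
# ---------------------------------------------------------------------------

def retention_factor(d_compound: float, d_front: float) -> float:
    """TLC retention factor: distance travelled by the compound over the
    distance travelled by the solvent front; dimensionless in [0, 1]."""
    if d_front <= 0:
        raise ValueError("solvent-front distance must be positive")
    if not 0 <= d_compound <= d_front:
        raise ValueError("compound distance must lie in [0, solvent front]")
    return d_compound / d_front


def hemolysis_inhibition(od1: float, od2: float, od3: float) -> float:
    """Percent inhibition of hypotonic hemolysis.

    od1: sample absorbance in isotonic solution; od2: sample in hypotonic
    solution; od3: hypotonic control.  Returns [1 - (od2-od1)/(od3-od1)] x 100.
    """
    if od3 == od1:
        raise ValueError("degenerate control: hypotonic control equals isotonic sample")
    return (1.0 - (od2 - od1) / (od3 - od1)) * 100.0


def percent_inhibition(control: float, sample: float) -> float:
    """(control - sample)/control x 100; used for DPPH scavenging and
    alpha-glucosidase inhibition alike."""
    if control <= 0:
        raise ValueError("control absorbance must be positive")
    return (control - sample) / control * 100.0


def wound_closure(area_t0: float, area_t: float) -> float:
    """Scratch-assay wound closure percent: (A0 - At)/A0 x 100."""
    if area_t0 <= 0:
        raise ValueError("initial wound area must be positive")
    if area_t < 0:
        raise ValueError("wound area cannot be negative")
    return (area_t0 - area_t) / area_t0 * 100.0


def selectivity_index(ic50_normal: float, ic50_cancer: float) -> float:
    """IC50 on normal cells divided by IC50 on cancer cells; > 1 means
    preferential toxicity to the cancer line."""
    if ic50_normal <= 0 or ic50_cancer <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_normal / ic50_cancer


# ---------------------------------------------------------------------------
# dose-response curves and IC50
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseCurve:
    """Concentration series with replicate-averaged percent responses.

    ``responses`` holds the per-concentration replicate mean; ``sd`` the
    replicate standard deviation (reporting only, not used in fitting).
    ``response_kind`` is "inhibition" (rising with dose) or "viability"
    (falling with dose).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    sd: np.ndarray | None = None
    response_kind: str = "inhibition"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.response_kind not in ("inhibition", "viability"):
            raise ValueError("response_kind must be 'inhibition' or 'viability'")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        if (np.diff(self.concentrations) <= 0).any():
            raise ValueError("concentrations must be sorted strictly ascending")
        if len(self.responses) != len(self.concentrations):
            raise ValueError("responses and concentrations differ in length")
        if not np.isfinite(self.responses).all():
            raise ValueError("responses must be finite")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if len(self.sd) != len(self.concentrations) or (self.sd < 0).any():
                raise ValueError("sd must be non-negative, one per concentration")

    @classmethod
    def from_replicates(cls, concentrations, replicates, response_kind="inhibition"
                        ) -> "DoseResponseCurve":
        """Average a (doses x replicates) percent matrix into a curve."""
        reps = np.asarray(replicates, dtype=float)
        sd = (reps.std(axis=1, ddof=1) if reps.shape[1] > 1
              else np.zeros(reps.shape[0]))
        return cls(concentrations=np.asarray(concentrations, float),
                   responses=reps.mean(axis=1), sd=sd,
                   response_kind=response_kind)


def _fourpl(logc: np.ndarray, bottom: float, top: float, logm: float, slope: float
            ) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (logm - logc)))


class FourParamLogistic(RegressorMixin, BaseEstimator):
    """Four-parameter logistic dose-response fit on log10 concentration.

    Model: y = bottom + (top - bottom) / (1 + 10^(slope (log10 m - log10 c))),
    with bottom/top bounded to [0, 100] percent and the inflection m
    strictly positive.  A positive slope gives a rising (inhibition) curve,
    a negative slope a falling (viability) curve.

    Attributes after fit: ``bottom_``, ``top_``, ``midpoint_`` (inflection
    concentration), ``hill_`` (slope) and ``ic50_`` (concentration at 50 %
    absolute response).
    """

    def __init__(self, loss_tol: float = 1e-8):
        self.loss_tol = loss_tol

    def fit(self, X, y):
        c = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float)
        if len(c) < 4:
            raise NotEstimableError("a 4PL fit needs at least 4 concentrations")
        if (c <= 0).any():
            raise ValueError("concentrations must be positive")
        logc = np.log10(c)
        rising = y[np.argmax(logc)] >= y[np.argmin(logc)]
        m0 = _interp_crossing(logc, y, 50.0)
        if m0 is None:
            m0 = float(logc.mean())
        x0 = np.array([max(y.min(), 0.0), min(y.max(), 100.0), m0,
                       1.0 if rising else -1.0])
        lo = np.array([0.0, 0.0, logc.min() - 3.0, -50.0])
        hi = np.array([100.0, 100.0, logc.max() + 3.0, 50.0])
        sol = least_squares(lambda p: _fourpl(logc, *p) - y,
                            np.clip(x0, lo, hi), bounds=(lo, hi),
                            xtol=self.loss_tol, ftol=self.loss_tol, gtol=self.loss_tol)
        self.bottom_, self.top_, logm, self.hill_ = (float(v) for v in sol.x)
        self.midpoint_ = 10.0 ** logm
        self.loss_ = float(sol.cost)
        self.converged_ = bool(sol.success)
        self.ic50_ = self._crossing_at(50.0)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "midpoint_")
        c = np.asarray(X, dtype=float).ravel()
        return _fourpl(np.log10(c), self.bottom_, self.top_,
                       math.log10(self.midpoint_), self.hill_)

    def _crossing_at(self, level: float) -> float | None:
        b, t, s = self.bottom_, self.top_, self.hill_
        if not (min(b, t) < level < max(b, t)) or s == 0:
            return None
        ratio = (t - level) / (level - b)
        return float(self.midpoint_ * 10.0 ** (-math.log10(ratio) / s))


def _interp_crossing(logc: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """log10 concentration at which the piecewise-linear curve first crosses
    *level*, or None if never bracketed."""
    for i in range(len(y) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            return float(logc[i] + (level - y0) / (y1 - y0) * (logc[i + 1] - logc[i]))
    return None


def estimate_ic50(curve: DoseResponseCurve, method: str = "4pl") -> float:
    """Concentration producing a 50 % response.

    The default path fits a four-parameter logistic on log10 concentration
    and solves the fitted curve for 50 %; ``method="interp"`` (also the
    fallback when the sigmoid fit cannot place the crossing) interpolates
    percent linearly in log10 concentration between the two observations
    bracketing 50 %.  Observed responses must bracket 50 %: an IC50
    extrapolated beyond the tested range is not reported.
    """
    y = curve.responses
    if not (y.min() < 50.0 < y.max() or (y == 50.0).any()):
        raise NotEstimableError(
            "responses never bracket 50%; IC50 is not estimable from this range")
    logc = np.log10(curve.concentrations)
    if method == "4pl" and len(curve.concentrations) >= 4:
        est = FourParamLogistic().fit(curve.concentrations, y)
        if est.ic50_ is not None and est.converged_:
            return est.ic50_
    crossing = _interp_crossing(logc, y, 50.0)
    if crossing is None:  # exact plateau at 50
        return float(curve.concentrations[np.argmin(np.abs(y - 50.0))])
    return float(10.0 ** crossing)


def mntd(curve: DoseResponseCurve, threshold: float = 90.0) -> float:
    """Maximum non-toxic dose: the largest tested concentration whose mean
    viability stays at or above *threshold* percent (default 90)."""
    if curve.response_kind != "viability":
        raise ValueError("MNTD is defined on a viability curve")
    ok = curve.concentrations[curve.responses >= threshold]
    if len(ok) == 0:
        raise NoNonToxicDoseError(
            f"no tested concentration keeps viability >= {threshold}%")
    return float(ok.max())


# ---------------------------------------------------------------------------
# broth microdilution
# ---------------------------------------------------------------------------

@dataclass
class PlateGrowthMatrix:
    """Growth flags of one pathogen across a dilution series.

    ``broth_growth[i]`` is True when visible growth occurred in the broth
    well at ``concentrations[i]``; ``subculture_growth[i]`` likewise for
    the agar subculture streak used for the bactericidal endpoint.
    """

    pathogen: str
    concentrations: np.ndarray
    broth_growth: np.ndarray
    subculture_growth: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.broth_growth = np.asarray(self.broth_growth, dtype=bool)
        self.subculture_growth = np.asarray(self.subculture_growth, dtype=bool)
        if (np.diff(self.concentrations) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")
        for flags in (self.broth_growth, self.subculture_growth):
            if len(flags) != len(self.concentrations):
                raise ValueError("growth flags must match the concentration series")


@dataclass
class MicMbcResult:
    """MIC/MBC endpoints; None means no inhibition within the tested range."""

    mic: float | None
    mbc: float | None
    max_tested: float

    def _label(self, v: float | None) -> str:
        return f"> {self.max_tested:g}" if v is None else f"{v:g}"

    @property
    def mic_text(self) -> str:
        return self._label(self.mic)

    @property
    def mbc_text(self) -> str:
        return self._label(self.mbc)


def mic_mbc(plate: PlateGrowthMatrix) -> MicMbcResult:
    """Minimum inhibitory and bactericidal concentrations from growth flags.

    MIC is the smallest concentration whose broth well shows no growth;
    MBC the smallest whose subculture shows no growth; an endpoint beyond
    the dilution series is reported as "> max tested".
    """
    def first_clear(flags: np.ndarray) -> float | None:
        idx = np.nonzero(~flags)[0]
        return float(plate.concentrations[idx[0]]) if len(idx) else None

    return MicMbcResult(mic=first_clear(plate.broth_growth),
                        mbc=first_clear(plate.subculture_growth),
                        max_tested=float(plate.concentrations[-1]))
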