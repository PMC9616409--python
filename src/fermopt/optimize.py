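"""Desirability-based maximization of a fitted response surface.

The Derringer-Suich desirability transform maps a predicted response y
onto [0, 1] relative to goal bounds L < U::

    d(y) = 0                        y <= L
         = ((y - L)/(U - L))^w     L < y < U
         = 1                        y >= U

For a single maximize goal, desirability is monotone in y, so maximizing
d over a box is equivalent to maximizing the predicted response itself;
the optimizer therefore searches the response surface directly and reports
the desirability of the optimum afterwards.

The search is deterministic: a coarse exhaustive grid over the box,
iterative zoom around the incumbent down to the requested resolution,
then a bounded quasi-Newton polish; ties break to the lexicographically
smallest coded point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .factors import FactorDefinition
from .surface import ResponseSurfaceRegressor

__all__ = [
    "DesirabilityGoal",
    "OptimizationResult",
    "desirability",
    "maximize_surface",
    "validation_error",
]


@dataclass(frozen=True)
class DesirabilityGoal:
    """A maximize goal with response bounds L < U and weight exponent w > 0."""

    lower: float
    upper: float
    weight: float = 1.0
    direction: str = "maximize"

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError("upper bound must exceed lower bound")
        if not self.weight > 0:
            raise ValueError("weight must be positive")
        if self.direction != "maximize":
            raise ValueError("only maximize goals are supported")


@dataclass
class OptimizationResult:
    """Optimum location and value in coded (and optionally actual) units."""

    coded_point: np.ndarray
    predicted_response: float
    desirability: float
    actual_point: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "coded_point": [float(v) for v in self.coded_point],
            "predicted_response": float(self.predicted_response),
            "desirability": float(self.desirability),
        }
        if self.actual_point is not None:
            out["actual_point"] = {k: float(v) for k, v in self.actual_point.items()}
        return out


def desirability(y: float, goal: DesirabilityGoal) -> float:
    """Derringer-Suich desirability of response *y* under a maximize goal."""
    if y <= goal.lower:
        return 0.0
    if y >= goal.upper:
        return 1.0
    return float(((y - goal.lower) / (goal.upper - goal.lower)) ** goal.weight)


def _grid_axes(region: np.ndarray, step: float) -> list[np.ndarray]:
    axes = []
    for lo, hi in region:
        n = int(round((hi - lo) / step)) + 1
        axes.append(np.linspace(lo, hi, max(n, 2)))
    return axes


def _best_on_grid(model, axes: list[np.ndarray]) -> tuple[float, np.ndarray]:
    """Exhaustive evaluation on the tensor grid; lexicographic tie-break."""
    pts = np.array(list(itertools.product(*axes)))
    vals = model.predict(pts)
    best = vals.max()
    cand = pts[np.isclose(vals, best, rtol=0, atol=1e-12)]
    order = np.lexsort(cand.T[::-1])
    return float(best), cand[order[0]]


def maximize_surface(model: ResponseSurfaceRegressor,
                     region: Sequence[tuple[float, float]] | None = None,
                     goal: DesirabilityGoal | None = None,
                     resolution: float = 0.01,
                     polish_tol: float = 1e-8,
                     coarse_budget: int = 200_000,
                     factors: Sequence[FactorDefinition] | None = None
                     ) -> OptimizationResult:
    """Maximize the predicted response over a coded box.

    Parameters
    ----------
    region : sequence of (low, high) per factor; defaults to the factorial
        cube [-1, +1]^k.
    goal : desirability goal; bounds default to the fitted response range.
    resolution : coded grid pitch of the final zoom stage.
    coarse_budget : maximum number of points evaluated per grid pass; the
        first pass coarsens its pitch to stay within budget, later passes
        zoom a shrinking neighbourhood of the incumbent until *resolution*
        is reached.
    factors : optional factor definitions used to report actual units.
    """
    k = model.n_features_in_
    if region is None:
        region = [(-1.0, 1.0)] * k
    region = np.asarray(region, dtype=float)
    if region.shape != (k, 2):
        raise ValueError(f"region must list (low, high) for each of {k} factors")
    if (region[:, 1] < region[:, 0]).any():
        raise ValueError("empty region: a lower bound exceeds its upper bound")

    # coarse pass: widest pitch not exceeding the point budget
    span = float((region[:, 1] - region[:, 0]).max())
    step = max(resolution, span / 2)
    while step > resolution:
        trial = step / 2
        n_pts = np.prod([int(round((hi - lo) / trial)) + 1 for lo, hi in region])
        if n_pts > coarse_budget:
            break
        step = trial
    best_val, best_pt = _best_on_grid(model, _grid_axes(region, step))

    # zoom passes: halve the pitch, search the +/- previous-pitch box
    while step > resolution:
        prev = step
        step = max(step / 4, resolution)
        local = np.column_stack([
            np.maximum(region[:, 0], best_pt - prev),
            np.minimum(region[:, 1], best_pt + prev),
        ])
        best_val, best_pt = _best_on_grid(model, _grid_axes(local, step))

    # bounded quasi-Newton polish
    res = minimize(lambda x: -model.predict(x), best_pt, method="L-BFGS-B",
                   bounds=[(lo, hi) for lo, hi in region],
                   options={"ftol": polish_tol, "gtol": 1e-12})
    if -res.fun > best_val:
        best_val, best_pt = float(-res.fun), np.clip(res.x, region[:, 0], region[:, 1])
    best_pt = np.round(best_pt / polish_tol) * polish_tol  # drop solver noise

    if goal is None:
        if hasattr(model, "_y"):
            goal = DesirabilityGoal(float(model._y.min()), float(model._y.max()))
        else:
            goal = DesirabilityGoal(0.0, max(best_val, 1.0))
    actual = None
    if factors is not None:
        actual = {f.name: float(f.decode(v)) for f, v in zip(factors, best_pt)}
    return OptimizationResult(coded_point=best_pt, predicted_response=best_val,
                              desirability=desirability(best_val, goal),
                              actual_point=actual)


def validation_error(actual: float, predicted: float) -> float:
    """Percent deviation of a confirmation run from the model prediction.

    Defined as 100 |predicted - actual| / predicted (denominator is the
    model prediction).
    """
    if predicted <= 0:
        raise ValueError("predicted response must be positive")
    return 100.0 * abs(predicted - actual) / predicted
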