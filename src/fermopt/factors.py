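"""Experimental factors and the coded <-> actual unit mapping.

A designed experiment is analysed in *coded* units: each factor is rescaled
so that its centre point is 0 and one design step is 1.  Two-level screening
designs use the codes -1/+1; central composite designs add axial points at
+/-alpha and centre points at 0.  The mapping is affine::

    actual = center + coded * step        (decode)
    coded  = (actual - center) / step     (code)

so regression coefficients on coded factors are directly comparable effect
sizes per design step.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

from pydantic import BaseModel, Field, model_validator

__all__ = ["FactorDefinition", "load_factor_definitions", "save_factor_definitions"]


class FactorDefinition(BaseModel):
    """One experimental factor with its unit and level mapping.

    Parameters
    ----------
    name : str
        Factor label, e.g. ``"peptone"``.
    unit : str
        Physical unit of the actual scale (g/l, degC, rpm, %, h, ...).
    center : float
        Actual value at coded 0.
    step : float
        Actual change per +1 coded unit; must be positive.
    alpha : float
        Coded magnitude of axial (star) points, default 2.  The five
        levels -alpha, -1, 0, +1, +alpha are therefore strictly
        increasing on the actual scale.
    """

    name: str
    unit: str = ""
    center: float
    step: float = Field(gt=0)
    alpha: float = Field(default=2.0, gt=0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _levels_increase(self) -> "FactorDefinition":
        levels = [self.decode(c) for c in (-self.alpha, -1.0, 0.0, 1.0, self.alpha)]
        if not all(a < b for a, b in zip(levels, levels[1:])):
            raise ValueError(f"factor {self.name!r}: levels are not strictly increasing")
        return self

    @classmethod
    def from_levels(cls, name: str, low: float, high: float, unit: str = "",
                    alpha: float = 2.0) -> "FactorDefinition":
        """Build from the actual values at coded -1 (*low*) and +1 (*high*)."""
        if not high > low:
            raise ValueError(f"factor {name!r}: high must exceed low")
        return cls(name=name, unit=unit, center=(low + high) / 2.0,
                   step=(high - low) / 2.0, alpha=alpha)

    def code(self, actual: float) -> float:
        """Map an actual value to coded units."""
        return (actual - self.center) / self.step

    def decode(self, coded: float) -> float:
        """Map a coded value back to actual units."""
        return self.center + coded * self.step

    def levels(self) -> dict[float, float]:
        """Actual values at the five canonical codes -alpha..+alpha."""
        return {c: self.decode(c) for c in (-self.alpha, -1.0, 0.0, 1.0, self.alpha)}


def code_value(factor: FactorDefinition, actual: float) -> float:
    """Coded level of *actual* under *factor*'s mapping."""
    return factor.code(actual)


def decode_value(factor: FactorDefinition, coded: float) -> float:
    """Actual value of *coded* under *factor*'s mapping."""
    return factor.decode(coded)


def load_factor_definitions(path: str | Path) -> list[FactorDefinition]:
    """Read a factor-definition config (JSON list of factor objects)."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError("factor config must be a JSON list of factor objects")
    return [FactorDefinition.model_validate(item) for item in raw]


def save_factor_definitions(factors: Iterable[FactorDefinition], path: str | Path) -> None:
    """Write factor definitions as a JSON config."""
    payload = [f.model_dump() for f in factors]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
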