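"""Two-level screening and central composite designs in coded units.

Plackett-Burman designs (PBD) estimate up to ``n_runs - 1`` main effects from
``n_runs`` runs (a multiple of 4) using a saturated orthogonal two-level
array built by cycling a known generator row and closing with an all-minus
run.  Central composite designs (CCD) support a full quadratic response
surface: a 2^k factorial block at -1/+1, 2k axial points at +/-alpha, and
replicated centre points at 0.  The *inscribed* variant (CCI) is obtained
purely through the factor-level mapping: the +/-alpha codes sit at the
experimental bounds, so every run stays inside the feasible region.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DesignCapacityError, UnsupportedRunCountError
from .factors import FactorDefinition

__all__ = [
    "DesignMatrix",
    "generate_plackett_burman",
    "generate_central_composite",
    "PB_GENERATORS",
    "rotatable_alpha",
]

# Classical cyclic generator rows (first run); the design cycles the row
# n_runs - 2 more times and appends an all-minus run.
PB_GENERATORS: dict[int, str] = {
    8: "+++-+--",
    12: "++-+++---+-",
    16: "++++-+-++--+---",
    20: "++--++++-+-+----++-",
    24: "+++++-+-++--++--+-+----",
}


def rotatable_alpha(k: int) -> float:
    """Axial distance making a CCD rotatable: (2^k)^(1/4); equals 2 at k=4."""
    return float(2 ** (k / 4.0))


def _default_names(k: int) -> list[str]:
    return [f"X{i + 1}" for i in range(k)]


@dataclass
class DesignMatrix:
    """Runs x factors in coded units, with design-type metadata.

    ``rows`` is a DataFrame indexed by 1-based run id with one column per
    factor.  Coded levels are stored as exact floats (integers and halves
    where possible) so orthogonality checks do not drift.
    """

    design_type: str  # "plackett_burman" | "central_composite"
    rows: pd.DataFrame
    n_center: int = 0
    alpha: float | None = None
    factor_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.design_type not in ("plackett_burman", "central_composite"):
            raise ValueError(f"unknown design_type {self.design_type!r}")
        self.rows = self.rows.astype(float)
        self.factor_names = list(self.rows.columns)

    # -- basic accessors -------------------------------------------------
    @property
    def n_runs(self) -> int:
        return len(self.rows)

    @property
    def k(self) -> int:
        return len(self.factor_names)

    def to_array(self) -> np.ndarray:
        return self.rows.to_numpy(dtype=float)

    # -- invariant checks ------------------------------------------------
    def validate(self) -> None:
        """Raise ValueError if the coded matrix violates its design invariants."""
        X = self.to_array()
        if self.design_type == "plackett_burman":
            if not np.isin(X, (-1.0, 1.0)).all():
                raise ValueError("PBD entries must all be -1 or +1")
            if (X.sum(axis=0) != 0).any():
                raise ValueError("PBD columns must balance +1 and -1 counts")
            G = X.T @ X
            off = G - np.diag(np.diag(G))
            if np.abs(off).max() > 0:
                raise ValueError("PBD columns must be mutually orthogonal")
        else:
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("central composite design requires alpha > 0")
            k = self.k
            is_fact = np.isin(X, (-1.0, 1.0)).all(axis=1)
            is_center = (X == 0).all(axis=1)
            axial_mask = ~is_fact & ~is_center
            if is_fact.sum() != 2 ** k:
                raise ValueError(f"expected {2 ** k} factorial runs, got {int(is_fact.sum())}")
            if is_center.sum() != self.n_center:
                raise ValueError("centre-run count does not match n_center")
            A = X[axial_mask]
            if len(A) != 2 * k:
                raise ValueError(f"expected {2 * k} axial runs, got {len(A)}")
            for row in A:
                nz = row[row != 0]
                if len(nz) != 1 or abs(nz[0]) != self.alpha:
                    raise ValueError("axial runs must have a single +/-alpha entry")

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path | io.TextIOBase,
               factors: Sequence[FactorDefinition] | None = None) -> None:
        """Write ``run,<factor...>`` CSV; pass *factors* to write actual units."""
        df = self.rows.copy()
        if factors is not None:
            by_name = {f.name: f for f in factors}
            for name in df.columns:
                df[name] = [by_name[name].decode(v) for v in df[name]]
        df.index.name = "run"
        df.to_csv(path)


def generate_plackett_burman(n_factors: int, n_runs: int = 12,
                             factor_names: Sequence[str] | None = None) -> DesignMatrix:
    """Generate a Plackett-Burman screening design.

    The classical construction cycles a generator row of length
    ``n_runs - 1`` and closes with an all-minus row, giving a saturated
    orthogonal array; the first *n_factors* columns are returned.

    Raises
    ------
    UnsupportedRunCountError
        If no cyclic generator is known for *n_runs*.
    DesignCapacityError
        If ``n_factors + 1 > n_runs``.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be positive")
    if n_runs % 4 != 0 or n_runs not in PB_GENERATORS:
        raise UnsupportedRunCountError(
            f"no cyclic Plackett-Burman generator for n_runs={n_runs}; "
            f"supported sizes: {sorted(PB_GENERATORS)}")
    if n_factors + 1 > n_runs:
        raise DesignCapacityError(
            f"{n_factors} factors need at least {n_factors + 1} runs; got {n_runs}")
    gen = np.array([1 if c == "+" else -1 for c in PB_GENERATORS[n_runs]], dtype=float)
    m = n_runs - 1
    body = np.array([[gen[(j - i) % m] for j in range(m)] for i in range(m)])
    full = np.vstack([body, -np.ones(m)])
    names = list(factor_names) if factor_names is not None else _default_names(n_factors)
    if len(names) != n_factors:
        raise ValueError("factor_names length must equal n_factors")
    rows = pd.DataFrame(full[:, :n_factors], columns=names,
                        index=pd.RangeIndex(1, n_runs + 1, name="run"))
    return DesignMatrix(design_type="plackett_burman", rows=rows)


def generate_central_composite(k: int, alpha: float | None = None, n_center: int = 6,
                               factor_names: Sequence[str] | None = None) -> DesignMatrix:
    """Generate a central composite design: factorial, then axial, then centre rows.

    *alpha* defaults to the rotatable value ``(2^k)^(1/4)``.
    """
    if k < 2:
        raise ValueError("central composite designs need k >= 2 factors")
    if n_center < 0:
        raise ValueError("n_center must be non-negative")
    if alpha is None:
        alpha = rotatable_alpha(k)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    # factorial block in standard (Yates) order: first column alternates fastest
    fact = np.array([[(i >> j & 1) * 2 - 1 for j in range(k)] for i in range(2 ** k)],
                    dtype=float)
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -alpha
        axial[2 * i + 1, i] = alpha
    center = np.zeros((n_center, k))
    X = np.vstack([fact, axial, center])
    names = list(factor_names) if factor_names is not None else _default_names(k)
    if len(names) != k:
        raise ValueError("factor_names length must equal k")
    rows = pd.DataFrame(X, columns=names,
                        index=pd.RangeIndex(1, len(X) + 1, name="run"))
    design = DesignMatrix(design_type="central_composite", rows=rows,
                          n_center=n_center, alpha=float(alpha))
    design.validate()
    return design
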