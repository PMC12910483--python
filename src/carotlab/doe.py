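"""Three-factor Box-Behnken designs and coded/actual level mapping.

A Box-Behnken design (BBD) for three factors places runs at the twelve
edge-midpoints of the factor cube -- every (±1, ±1) combination of each
factor pair with the third factor at its center -- plus replicated center
points.  With three center replicates this is the classical 15-run design
used for second-order response-surface fitting.

Factor levels are expressed on the coded −1/0/+1 scale.  The coded↔actual
mapping is piecewise linear, anchored at (−1, 0, +1) → (low, center, high),
so asymmetric spacing (center not midway between low and high) is supported
when explicitly enabled on the :class:`FactorSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, OutOfRangeError, ValidationError

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "DesignMatrix",
    "build_bbd",
    "code_to_actual",
    "actual_to_code",
]

#: Allowed coded levels under strict validation.
CODED_LEVELS = (-1.0, 0.0, 1.0)


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its low/center/high actual settings.

    Parameters
    ----------
    name : str
        Nonempty factor name (e.g. ``"cheese_whey"``).
    low, center, high : float
        Actual settings mapped to coded −1, 0, +1.  Must be strictly
        increasing.  Unless ``asymmetric=True``, ``center`` must equal
        ``(low + high) / 2`` to a relative tolerance of 1e−9.
    units : str
        Free-text units, e.g. ``"% v/v"`` or ``"g% w/v"``.
    asymmetric : bool
        Allow a center point off the midpoint of ``[low, high]``.
    """

    name: str
    low: float
    center: float
    high: float
    units: str = ""
    asymmetric: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("FactorSpec.name must be nonempty")
        for fld in ("low", "center", "high"):
            v = getattr(self, fld)
            if not np.isfinite(v):
                raise ValidationError(
                    f"factor {self.name!r}: field {fld!r} must be finite, got {v!r}"
                )
        if not (self.low < self.center < self.high):
            raise ValidationError(
                f"factor {self.name!r}: require low < center < high, "
                f"got {self.low} / {self.center} / {self.high}"
            )
        if not self.asymmetric:
            mid = 0.5 * (self.low + self.high)
            scale = max(abs(self.low), abs(self.high), 1e-300)
            if abs(self.center - mid) > 1e-9 * scale:
                raise ValidationError(
                    f"factor {self.name!r}: center {self.center} is not the midpoint "
                    f"{mid} of [low, high]; pass asymmetric=True to allow this"
                )


@dataclass(frozen=True)
class DesignPoint:
    """A single run: coded levels and the actual settings they map to."""

    run_id: int
    coded: tuple[float, float, float]
    actual: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.run_id < 1:
            raise ValidationError(f"run_id must be positive, got {self.run_id}")
        if len(self.coded) != 3 or len(self.actual) != 3:
            raise ValidationError("DesignPoint requires 3 coded and 3 actual levels")


@dataclass(frozen=True)
class DesignMatrix:
    """An ordered 3-factor Box-Behnken design.

    Invariants checked at construction: run count is ``12 + n_center``;
    exactly ``n_center`` all-zero coded runs; each factor pair contributes
    the four (±1, ±1) sign combinations exactly once with the third factor
    at 0; every coded column sums to zero.
    """

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    points: tuple[DesignPoint, ...]
    n_center: int
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.factors) != 3:
            raise DesignError("exactly 3 factors required")
        if self.validate:
            self._check_structure()

    def _check_structure(self) -> None:
        coded = self.coded()
        n = len(self.points)
        if n != 12 + self.n_center:
            raise DesignError(
                f"run count {n} != 12 + n_center ({12 + self.n_center})"
            )
        center_mask = np.all(coded == 0.0, axis=1)
        if int(center_mask.sum()) != self.n_center:
            raise DesignError(
                f"expected {self.n_center} center runs, found {int(center_mask.sum())}"
            )
        for i, j in combinations(range(3), 2):
            k = 3 - i - j
            on_edge = coded[(coded[:, k] == 0.0) & ~center_mask]
            combos = {(int(r[i]), int(r[j])) for r in on_edge}
            counts = [
                int(np.sum((on_edge[:, i] == si) & (on_edge[:, j] == sj)))
                for si in (-1, 1)
                for sj in (-1, 1)
            ]
            if combos != {(-1, -1), (-1, 1), (1, -1), (1, 1)} or counts != [1, 1, 1, 1]:
                raise DesignError(
                    f"factor pair ({i}, {j}) does not contribute the four "
                    "(±1, ±1) edge-midpoint runs exactly once"
                )
        sums = coded.sum(axis=0)
        if np.any(sums != 0.0):
            raise DesignError(f"coded columns must each sum to 0, got {sums.tolist()}")

    @property
    def n_runs(self) -> int:
        return len(self.points)

    def coded(self) -> np.ndarray:
        """(n_runs, 3) array of coded levels, in design order."""
        return np.array([p.coded for p in self.points], dtype=float)

    def actual(self) -> np.ndarray:
        """(n_runs, 3) array of actual settings, in design order."""
        return np.array([p.actual for p in self.points], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with both coded and actual columns."""
        coded = self.coded()
        actual = self.actual()
        data: dict[str, object] = {"run": [p.run_id for p in self.points]}
        for i in range(3):
            data[f"x{i + 1}_coded"] = coded[:, i]
        for i, f in enumerate(self.factors):
            data[f"{f.name}_actual"] = actual[:, i]
        return pd.DataFrame(data)


def code_to_actual(coded: float, spec: FactorSpec) -> float:
    """Map a coded level to the actual factor setting.

    Piecewise linear: ``center + coded*(high - center)`` for ``coded >= 0``
    and ``center + coded*(center - low)`` for ``coded < 0``.  The two
    branches coincide for symmetric level spacing.
    """
    if coded >= 0:
        return spec.center + coded * (spec.high - spec.center)
    return spec.center + coded * (spec.center - spec.low)


def actual_to_code(actual: float, spec: FactorSpec) -> float:
    """Exact inverse of :func:`code_to_actual` on ``[low, high]``.

    Raises
    ------
    OutOfRangeError
        If ``actual`` lies outside ``[low, high]`` (no silent extrapolation).
    """
    if not (spec.low <= actual <= spec.high):
        raise OutOfRangeError(
            f"factor {spec.name!r}: actual value {actual} outside "
            f"[{spec.low}, {spec.high}]"
        )
    if actual >= spec.center:
        return (actual - spec.center) / (spec.high - spec.center)
    return (actual - spec.center) / (spec.center - spec.low)


def _edge_midpoints() -> list[tuple[float, float, float]]:
    # Canonical order: pair (X1,X2), then (X1,X3), then (X2,X3);
    # within each pair, signs in (-,-), (+,-), (-,+), (+,+) order.
    pts: list[tuple[float, float, float]] = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for sj in (-1.0, 1.0):
            for si in (-1.0, 1.0):
                p = [0.0, 0.0, 0.0]
                p[i], p[j] = si, sj
                pts.append((p[0], p[1], p[2]))
    return pts


def build_bbd(
    factors: Sequence[FactorSpec], n_center: int = 3
) -> DesignMatrix:
    """Construct the canonical 3-factor Box-Behnken design.

    Run order is deterministic: the 12 edge-midpoints in the documented
    pair order, then ``n_center`` center replicates.

    Parameters
    ----------
    factors : sequence of 3 FactorSpec
    n_center : int
        Number of center replicates (>= 1).  The classical design uses 3,
        giving 15 runs.
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise ValidationError(f"exactly 3 factors required, got {len(factors)}")
    if n_center < 1:
        raise ValidationError(f"n_center must be >= 1, got {n_center}")
    coded_rows = _edge_midpoints() + [(0.0, 0.0, 0.0)] * n_center
    points = tuple(
        DesignPoint(
            run_id=k + 1,
            coded=row,
            actual=tuple(code_to_actual(c, f) for c, f in zip(row, factors)),
        )
        for k, row in enumerate(coded_rows)
    )
    return DesignMatrix(factors=factors, points=points, n_center=n_center)


def validate_coded_levels(coded: np.ndarray, strict: bool = True) -> None:
    """Check coded entries against {−1, 0, +1} (strict) or [−1, 1] (relaxed)."""
    arr = np.asarray(coded, dtype=float)
    if strict:
        bad = ~np.isin(arr, CODED_LEVELS)
        if np.any(bad):
            rows, cols = np.nonzero(np.atleast_2d(bad))
            raise DesignError(
                "coded levels must be in {-1, 0, 1} under strict validation; "
                f"first offending entry at row {rows[0]}, column {cols[0]}"
            )
    elif np.any((arr < -1.0) | (arr > 1.0)):
        raise DesignError("coded levels must lie in [-1, 1]")
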