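"""Carotenoid quantification and stability residuals.

Quantification uses the percentage extinction coefficient (E1%, 1 cm)
convention: E1% is the absorbance of a 1 g per 100 mL solution across a
1 cm path, so a measured absorbance A at the pigment's λmax (435 nm here)
with dilution factor DF converts to concentration

    C (mg/mL) = A * DF * 10 / E1%.

The default E1% of 2500 is the generic carotenoid value and is fully
configurable — absolute yields depend on it.

Stability is summarized as the residual percentage 100 * Ct / C0 of a
stressed sample against its control; values above 100% (absorbance
enhancement, e.g. under acidic pH) are legitimate and passed through.
A sample destroyed by the treatment (visible precipitation, no reading)
is an explicit not-detected marker, represented as ``None``, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError

__all__ = [
    "LAMBDA_MAX_NM",
    "DEFAULT_E1PCT",
    "ExtinctionQuantification",
    "StabilityMeasurement",
    "quantify",
    "residual_stability",
    "stability_report",
]

#: Absorption maximum of the pigment extract (nm), carried as metadata.
LAMBDA_MAX_NM = 435.0

#: Generic carotenoid percentage extinction coefficient (1 g/100 mL, 1 cm).
DEFAULT_E1PCT = 2500.0


@dataclass(frozen=True)
class ExtinctionQuantification:
    absorbance: float
    dilution_factor: float
    extinction_1pct: float
    concentration: float  # mg/mL
    lambda_max_nm: float = LAMBDA_MAX_NM


@dataclass(frozen=True)
class StabilityMeasurement:
    """One stressed-vs-control reading; ``ct=None`` means not detected."""

    condition: str
    c0: float
    ct: float | None

    @property
    def residual_pct(self) -> float | None:
        return residual_stability(self.c0, self.ct)


def quantify(
    absorbance: float,
    dilution_factor: float = 1.0,
    extinction_1pct: float = DEFAULT_E1PCT,
) -> ExtinctionQuantification:
    """Convert absorbance at λmax to pigment concentration (mg/mL)."""
    for name, v in (
        ("absorbance", absorbance),
        ("dilution_factor", dilution_factor),
        ("extinction_1pct", extinction_1pct),
    ):
        if not v > 0:
            raise DomainError(f"{name} must be positive, got {v}")
    conc = absorbance * dilution_factor * 10.0 / extinction_1pct
    return ExtinctionQuantification(
        absorbance=absorbance,
        dilution_factor=dilution_factor,
        extinction_1pct=extinction_1pct,
        concentration=conc,
    )


def residual_stability(c0: float, ct: float | None) -> float | None:
    """Residual% = 100 * Ct / C0; not-detected (None) passes through."""
    if not c0 > 0:
        raise DomainError(f"control value c0 must be positive, got {c0}")
    if ct is None:
        return None
    return 100.0 * ct / c0


def stability_report(
    measurements: Sequence[StabilityMeasurement],
    full_stability_threshold: float = 95.0,
) -> pd.DataFrame:
    """Per-condition residual% summary with a stability flag.

    Replicates of the same condition are aggregated as mean ± standard
    error.  Conditions are flagged ``stable`` when the mean residual is at
    or above the threshold, ``partial`` below it, and ``not_detected``
    when every replicate is a not-detected marker (such conditions are
    excluded from the numeric summary, not zero-filled).
    """
    if not measurements:
        raise ValidationError("at least one stability measurement required")
    rows = []
    order: list[str] = []
    by_cond: dict[str, list[float | None]] = {}
    for m in measurements:
        if m.condition not in by_cond:
            order.append(m.condition)
            by_cond[m.condition] = []
        by_cond[m.condition].append(m.residual_pct)
    for cond in order:
        vals = [v for v in by_cond[cond] if v is not None]
        n_nd = len(by_cond[cond]) - len(vals)
        if not vals:
            rows.append(
                {
                    "condition": cond,
                    "n": 0,
                    "n_not_detected": n_nd,
                    "mean_residual_pct": np.nan,
                    "se_residual_pct": np.nan,
                    "status": "not_detected",
                }
            )
            continue
        arr = np.asarray(vals)
        mean = float(arr.mean())
        se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else np.nan
        status = "stable" if mean >= full_stability_threshold else "partial"
        rows.append(
            {
                "condition": cond,
                "n": len(vals),
                "n_not_detected": n_nd,
                "mean_residual_pct": mean,
                "se_residual_pct": se,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
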