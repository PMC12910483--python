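"""Antioxidant, cytotoxicity and selectivity analytics.

Three assay families are covered:

* DPPH radical scavenging: RSA% = 100 * (A_control − A_sample) / A_control
  at 517 nm, time-resolved per concentration, with the IC50 found by
  log-dose linear interpolation between the two concentrations bracketing
  50% scavenging.

* MTT viability and the median-effect dose-response model.  The
  mass-action median-effect relation fa/fu = (D/Dm)^m links the fraction
  affected fa (= 1 − viability/100) to dose D through the median-effect
  dose Dm (the IC50) and slope m.  Taking logs gives the linear
  "median-effect plot" log10(fa/(1−fa)) = m*log10(D) − m*log10(Dm), fit
  here by unweighted OLS after excluding logit-degenerate points.

* Selectivity index SI = IC50(normal reference cells) / IC50(cell line),
  classified under the common literature threshold schemes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import DomainError, InsufficientDataError, ValidationError

__all__ = [
    "ScavengingSeries",
    "DoseResponseSeries",
    "MedianEffectFit",
    "MedianEffectModel",
    "DpphEstimate",
    "rsa_percent",
    "dpph_ic50",
    "viability_percent",
    "median_effect_fit",
    "selectivity_index",
    "classify_selectivity",
    "selectivity_report",
    "net_inhibition_zone",
    "SELECTIVITY_SCHEMES",
]

#: SI threshold schemes found in the natural-product literature:
#: (threshold, inclusive?) — "ge2" means selective when SI >= 2, "gt1"
#: strictly greater than 1.
SELECTIVITY_SCHEMES = {
    "gt1": (1.0, False),
    "ge2": (2.0, True),
    "ge3": (3.0, True),
    "ge10": (10.0, True),
}


@dataclass(frozen=True)
class ScavengingSeries:
    """Time course of DPPH absorbances for one extract concentration."""

    concentration: float  # μg/mL
    time_min: tuple[float, ...]
    a_control: tuple[float, ...]  # AU at 517 nm
    a_sample: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.time_min)
        if len(self.a_control) != n or len(self.a_sample) != n:
            raise ValidationError("time/control/sample lengths must match")
        if any(t2 <= t1 for t1, t2 in zip(self.time_min, self.time_min[1:])):
            raise ValidationError("time points must be strictly increasing")
        if any(a < 0 for a in self.a_control + self.a_sample):
            raise ValidationError("absorbances must be non-negative")

    def rsa_at(self, t: float) -> float:
        """RSA% at time ``t``, linearly interpolated between time points."""
        times = np.asarray(self.time_min)
        if not (times[0] <= t <= times[-1]):
            raise ValidationError(
                f"time {t} outside measured window [{times[0]}, {times[-1]}]"
            )
        rsa = np.array(
            [rsa_percent(ac, asamp) for ac, asamp in zip(self.a_control, self.a_sample)]
        )
        return float(np.interp(t, times, rsa))


@dataclass(frozen=True)
class DoseResponseSeries:
    """MTT viability series for one agent/cell-line combination."""

    agent: str
    cell_line: str
    doses: tuple[float, ...]  # mg/mL, strictly increasing
    viability_pct: tuple[float, ...]
    exposure_h: float = 48.0

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.viability_pct):
            raise ValidationError("doses and viability lengths must match")
        if any(d <= 0 for d in self.doses):
            raise ValidationError("doses must be strictly positive")
        if any(d2 <= d1 for d1, d2 in zip(self.doses, self.doses[1:])):
            raise ValidationError("doses must be strictly increasing")
        if not all(np.isfinite(v) for v in self.viability_pct):
            raise ValidationError("viability must be finite")


@dataclass(frozen=True)
class MedianEffectFit:
    """Result of the log-linearized median-effect fit."""

    m: float  # median-effect slope
    dm: float  # median-effect dose = IC50 (dose units)
    r: float  # correlation of the linearized plot
    n_used: int
    excluded: tuple[int, ...]  # dose indices dropped by the fa exclusion rule


@dataclass(frozen=True)
class DpphEstimate:
    """DPPH IC50 estimate; ``ic50`` is None when 50% RSA is never reached."""

    ic50: float | None  # μg/mL
    reached: bool
    at_time_min: float
    max_rsa_pct: float
    rsa_by_concentration: tuple[tuple[float, float], ...]  # (conc, RSA%)


def rsa_percent(a_control: float, a_sample: float) -> float:
    """Radical-scavenging activity %: 100*(A_control − A_sample)/A_control.

    Negative values (pro-oxidant artifact) are passed through with a
    warning rather than clipped.
    """
    if not a_control > 0:
        raise DomainError(f"a_control must be positive, got {a_control}")
    rsa = 100.0 * (a_control - a_sample) / a_control
    if rsa < 0:
        warnings.warn(
            f"negative scavenging ({rsa:.2f}%): sample absorbance exceeds control",
            stacklevel=2,
        )
    return rsa


def viability_percent(a_treated: float, a_untreated: float) -> float:
    """MTT viability %: 100 * A_treated / A_untreated (background-corrected)."""
    if not a_untreated > 0:
        raise DomainError(f"a_untreated must be positive, got {a_untreated}")
    return 100.0 * a_treated / a_untreated


def dpph_ic50(
    series: Sequence[ScavengingSeries], at_time: float = 30.0
) -> DpphEstimate:
    """IC50 of radical scavenging at a fixed incubation time.

    RSA% is computed per concentration at ``at_time`` (interpolating the
    time course where needed); the IC50 is interpolated linearly on
    log10(concentration) between the two concentrations bracketing 50%.
    If a tabulated concentration hits exactly 50% it is returned as-is;
    if 50% is never attained a not-reached estimate is returned carrying
    the maximum RSA% achieved.
    """
    if len(series) < 2:
        raise ValidationError("at least 2 concentrations required")
    pairs = sorted(
        ((s.concentration, s.rsa_at(at_time)) for s in series), key=lambda p: p[0]
    )
    concs = np.array([p[0] for p in pairs])
    rsa = np.array([p[1] for p in pairs])
    if np.any(concs <= 0):
        raise DomainError("concentrations must be positive")
    exact = np.isclose(rsa, 50.0, atol=1e-12)
    if np.any(exact):
        ic50 = float(concs[np.nonzero(exact)[0][0]])
        return DpphEstimate(ic50, True, at_time, float(rsa.max()), tuple(pairs))
    above = rsa >= 50.0
    if not np.any(above):
        return DpphEstimate(None, False, at_time, float(rsa.max()), tuple(pairs))
    hi = int(np.argmax(above))  # first concentration at/above 50%
    if hi == 0:  # even the lowest concentration scavenges > 50%
        return DpphEstimate(float(concs[0]), True, at_time, float(rsa.max()), tuple(pairs))
    lo = hi - 1
    logc = np.log10(concs)
    frac = (50.0 - rsa[lo]) / (rsa[hi] - rsa[lo])
    ic50 = float(10 ** (logc[lo] + frac * (logc[hi] - logc[lo])))
    return DpphEstimate(ic50, True, at_time, float(rsa.max()), tuple(pairs))


class MedianEffectModel(BaseEstimator):
    """Mass-action median-effect dose-response estimator.

    ``fit(doses, viability_pct)`` linearizes fa/(1−fa) = (D/Dm)^m on
    log10 scale and solves by unweighted OLS.  Points whose fraction
    affected falls outside ``(fa_min, fa_max)`` are excluded (the logit
    blows up) and reported via ``excluded_``.

    Attributes
    ----------
    m_ : float
        Median-effect slope.
    dm_ : float
        Median-effect dose (= IC50) in the dose units.
    r_ : float
        Pearson correlation of the linearized plot.
    n_used_ : int
    excluded_ : tuple of int
    """

    def __init__(self, fa_min: float = 0.001, fa_max: float = 0.999):
        self.fa_min = fa_min
        self.fa_max = fa_max

    def fit(self, doses, viability_pct):
        doses = np.asarray(doses, dtype=float).ravel()
        viab = np.asarray(viability_pct, dtype=float).ravel()
        if len(doses) != len(viab):
            raise ValidationError("doses and viability lengths must match")
        if np.any(doses <= 0):
            raise DomainError("doses must be strictly positive")
        fa = 1.0 - viab / 100.0
        usable = (fa > self.fa_min) & (fa < self.fa_max) & np.isfinite(fa)
        self.excluded_ = tuple(int(i) for i in np.nonzero(~usable)[0])
        if int(usable.sum()) < 2:
            raise InsufficientDataError(
                f"only {int(usable.sum())} usable dose point(s) after excluding "
                f"fa outside ({self.fa_min}, {self.fa_max}); >= 2 required"
            )
        x = np.log10(doses[usable])
        y = np.log10(fa[usable] / (1.0 - fa[usable]))
        res = stats.linregress(x, y)
        self.m_ = float(res.slope)
        self.dm_ = float(10 ** (-res.intercept / res.slope))
        self.r_ = float(res.rvalue)
        self.n_used_ = int(usable.sum())
        return self

    def predict_fa(self, doses) -> np.ndarray:
        """Fraction affected at given doses under the fitted model."""
        d = np.asarray(doses, dtype=float)
        return 1.0 / (1.0 + (self.dm_ / d) ** self.m_)

    @property
    def ic50_(self) -> float:
        return self.dm_


def median_effect_fit(series: DoseResponseSeries) -> MedianEffectFit:
    """Fit the median-effect model to one dose-response series."""
    est = MedianEffectModel().fit(series.doses, series.viability_pct)
    return MedianEffectFit(
        m=est.m_, dm=est.dm_, r=est.r_, n_used=est.n_used_, excluded=est.excluded_
    )


def selectivity_index(ic50_reference: float, ic50_line: float) -> float:
    """SI = IC50(reference normal cells) / IC50(cell line)."""
    if not ic50_reference > 0 or not ic50_line > 0:
        raise DomainError("both IC50 values must be positive")
    return ic50_reference / ic50_line


def classify_selectivity(si: float, scheme: str = "ge2") -> str:
    """Classify an SI value as "selective"/"non-selective" under a scheme."""
    if not si > 0:
        raise DomainError(f"SI must be positive, got {si}")
    if scheme not in SELECTIVITY_SCHEMES:
        raise ValidationError(
            f"unknown scheme {scheme!r}; choose from {sorted(SELECTIVITY_SCHEMES)}"
        )
    threshold, inclusive = SELECTIVITY_SCHEMES[scheme]
    selective = si >= threshold if inclusive else si > threshold
    return "selective" if selective else "non-selective"


def selectivity_report(
    ic50_reference: float,
    ic50_by_line: dict[str, float],
    scheme: str = "ge2",
) -> dict[str, dict[str, float | str]]:
    """Per-cell-line IC50, SI and classification under one scheme."""
    out: dict[str, dict[str, float | str]] = {}
    for line, ic50 in ic50_by_line.items():
        si = selectivity_index(ic50_reference, ic50)
        out[line] = {
            "ic50": ic50,
            "si": si,
            "classification": classify_selectivity(si, scheme),
        }
    return out


def net_inhibition_zone(total_zone_mm: float, well_diameter_mm: float) -> float:
    """Net clearing of an agar-well diffusion assay: total − well diameter."""
    if well_diameter_mm < 0:
        raise DomainError("well diameter must be non-negative")
    if total_zone_mm < well_diameter_mm:
        raise DomainError(
            f"total zone {total_zone_mm} mm smaller than well {well_diameter_mm} mm"
        )
    return total_zone_mm - well_diameter_mm
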