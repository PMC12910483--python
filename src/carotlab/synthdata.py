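"""Seeded synthetic datasets with the statistical structure each stage assumes.

Every generator draws from the closed-form model its downstream analysis
fits, plus explicit noise, so parameter-recovery and calibration studies
run with known ground truth and no external data:

* Box-Behnken responses: known second-order polynomial on the coded
  design plus i.i.d. Gaussian noise.
* Dose-response: mass-action median-effect curves fa = 1/(1+(Dm/D)^m)
  with truncated Gaussian viability noise.
* DPPH kinetics: first-order approach to a concentration-dependent
  plateau, RSA(c, t) = plateau(c) * (1 − exp(−rate*t)), with plateau a
  Hill function crossing 50% at the configured IC50.
* Stability: per-condition decay (or enhancement) fractions, including
  explicit not-detected conditions.

A single root seed fans out deterministically to per-generator streams
(one ``SeedSequence`` child per generator, fixed order), so adding a
generator never perturbs existing outputs.  Default parameter values are
the study conditions of the packaged 15-run fermentation dataset: the
fitted surface coefficients as truth, noise SD equal to the root of the
fit's residual mean square, the printed twofold MTT dilution series and
IC50s, and the published stability pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bioassay import DoseResponseSeries, ScavengingSeries
from .doe import DesignMatrix
from .exceptions import ValidationError
from .pigment import StabilityMeasurement
from .rsm import quadratic_terms

__all__ = [
    "GENERATOR_VERSION",
    "BBDSimConfig",
    "DoseResponseSimConfig",
    "DpphSimConfig",
    "StabilitySimConfig",
    "SimulationConfig",
    "simulate_bbd_response",
    "simulate_dose_response",
    "simulate_dpph",
    "simulate_stability",
]

#: Bump when any generator's draw sequence changes.
GENERATOR_VERSION = 1

# Fitted second-order surface of the packaged 15-run design (coefficients
# in TERM_NAMES order) — the data-generating truth for BBD simulations.
STUDY_SURFACE_BETA = (
    0.022,
    0.0068875,
    -0.0066125,
    0.002475,
    -0.013125,
    -0.00065,
    0.00655,
    0.0024625,
    0.0049125,
    -0.0064625,
)

#: Residual SD of the packaged fit (root of its residual mean square).
STUDY_NOISE_SD = float(np.sqrt(6.67e-05))

#: Twofold MTT dilution series used in the study, mg/mL (ascending).
STUDY_MTT_DOSES = tuple(5.6 / 2**k for k in reversed(range(8)))

# Published per-condition stability pattern (residual fraction of control;
# None = not detected).
STUDY_STABILITY_PATTERN = {
    "pH 3": 3.105,
    "pH 4": 1.12,
    "pH 5": 1.08,
    "pH 6": 0.637,
    "pH 7": 0.415,
    "pH 8": None,
    "pH 9": None,
    "20 C": 0.99,
    "30 C": 1.15,
    "40 C": 1.04,
    "50 C": 1.025,
    "60 C": 0.625,
    "70 C": 0.52,
    "daylight": 0.26,
}


@dataclass(frozen=True)
class BBDSimConfig:
    true_beta: tuple[float, ...] = STUDY_SURFACE_BETA
    noise_sd: float = STUDY_NOISE_SD
    n_center: int = 3

    def __post_init__(self) -> None:
        if len(self.true_beta) != 10:
            raise ValidationError("true_beta must hold 10 coefficients")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class DoseResponseSimConfig:
    m: float = 2.0
    dm: float = 0.56  # mg/mL
    doses: tuple[float, ...] = STUDY_MTT_DOSES
    viability_noise_sd: float = 2.0  # percentage points, multiplicative-free
    agent: str = "carotenoid extract"
    cell_line: str = "HCT-116"

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValidationError("doses must be positive")
        if self.m == 0:
            raise ValidationError("slope m must be nonzero")
        if self.viability_noise_sd < 0:
            raise ValidationError("viability_noise_sd must be >= 0")


@dataclass(frozen=True)
class DpphSimConfig:
    ic50: float = 6.0  # μg/mL
    hill: float = 1.5
    plateau_top: float = 95.0  # % RSA as t -> inf at saturating concentration
    rate_per_min: float = 0.12
    concentrations: tuple[float, ...] = (1.2, 3.0, 6.0)
    time_points: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0)
    a_control: float = 0.8  # AU at 517 nm
    noise_sd: float = 0.0  # absorbance noise, AU

    def __post_init__(self) -> None:
        if self.plateau_top <= 50.0:
            raise ValidationError("plateau_top must exceed 50% for the IC50 to exist")
        if self.ic50 <= 0 or self.rate_per_min <= 0 or self.hill <= 0:
            raise ValidationError("ic50, rate and hill must be positive")

    def plateau(self, c: float) -> float:
        """Asymptotic RSA% at concentration c; crosses 50% at ``ic50``."""
        k = self.ic50 * (self.plateau_top / 50.0 - 1.0) ** (1.0 / self.hill)
        return self.plateau_top * c**self.hill / (c**self.hill + k**self.hill)


@dataclass(frozen=True)
class StabilitySimConfig:
    decay_fraction: dict[str, float | None] = field(
        default_factory=lambda: dict(STUDY_STABILITY_PATTERN)
    )
    c0: float = 1.0
    noise_sd: float = 0.0
    n_replicates: int = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Root configuration: one seed, one sub-config per generator."""

    seed: int = 0
    bbd: BBDSimConfig = field(default_factory=BBDSimConfig)
    dose_response: DoseResponseSimConfig = field(default_factory=DoseResponseSimConfig)
    dpph: DpphSimConfig = field(default_factory=DpphSimConfig)
    stability: StabilitySimConfig = field(default_factory=StabilitySimConfig)

    def rng(self, stream: str) -> np.random.Generator:
        """Per-generator RNG stream derived from the root seed."""
        streams = ("bbd", "dose_response", "dpph", "stability")
        if stream not in streams:
            raise ValidationError(f"unknown stream {stream!r}")
        children = np.random.SeedSequence(self.seed).spawn(len(streams))
        return np.random.default_rng(children[streams.index(stream)])


def simulate_bbd_response(
    config: SimulationConfig, design: DesignMatrix
) -> np.ndarray:
    """Responses = known polynomial at each coded point + N(0, noise_sd)."""
    cfg = config.bbd
    mean = quadratic_terms(design.coded()) @ np.asarray(cfg.true_beta)
    rng = config.rng("bbd")
    return mean + rng.normal(0.0, cfg.noise_sd, size=len(mean))


def simulate_dose_response(config: SimulationConfig) -> DoseResponseSeries:
    """Median-effect viability curve with truncated Gaussian noise.

    fa = 1/(1+(Dm/D)^m); viability% = 100*(1−fa) + noise, clipped to
    [0, 100].  At D = Dm the noiseless viability is exactly 50%.
    """
    cfg = config.dose_response
    d = np.asarray(cfg.doses)
    fa = 1.0 / (1.0 + (cfg.dm / d) ** cfg.m)
    viab = 100.0 * (1.0 - fa)
    if cfg.viability_noise_sd > 0:
        rng = config.rng("dose_response")
        viab = np.clip(
            viab + rng.normal(0.0, cfg.viability_noise_sd, size=len(viab)), 0.0, 100.0
        )
    return DoseResponseSeries(
        agent=cfg.agent,
        cell_line=cfg.cell_line,
        doses=tuple(float(x) for x in d),
        viability_pct=tuple(float(v) for v in viab),
    )


def simulate_dpph(config: SimulationConfig) -> list[ScavengingSeries]:
    """First-order scavenging kinetics approaching a Hill plateau.

    RSA%(c, t) = plateau(c) * (1 − exp(−rate*t)), converted back to
    absorbance pairs with a fixed control absorbance.
    """
    cfg = config.dpph
    rng = config.rng("dpph")
    out = []
    t = np.asarray(cfg.time_points)
    for c in cfg.concentrations:
        rsa = cfg.plateau(c) * (1.0 - np.exp(-cfg.rate_per_min * t))
        a_sample = cfg.a_control * (1.0 - rsa / 100.0)
        if cfg.noise_sd > 0:
            a_sample = np.clip(
                a_sample + rng.normal(0.0, cfg.noise_sd, size=len(t)), 0.0, None
            )
        out.append(
            ScavengingSeries(
                concentration=float(c),
                time_min=tuple(float(x) for x in t),
                a_control=(float(cfg.a_control),) * len(t),
                a_sample=tuple(float(a) for a in a_sample),
            )
        )
    return out


def simulate_stability(config: SimulationConfig) -> list[StabilityMeasurement]:
    """Per-condition treated readings ct = c0 * fraction + noise; ND propagates."""
    cfg = config.stability
    rng = config.rng("stability")
    out = []
    for cond, frac in cfg.decay_fraction.items():
        for _ in range(cfg.n_replicates):
            if frac is None:
                out.append(StabilityMeasurement(condition=cond, c0=cfg.c0, ct=None))
                continue
            ct = cfg.c0 * frac
            if cfg.noise_sd > 0:
                ct = max(0.0, ct + rng.normal(0.0, cfg.noise_sd))
            out.append(StabilityMeasurement(condition=cond, c0=cfg.c0, ct=ct))
    return out
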