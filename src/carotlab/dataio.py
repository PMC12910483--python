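"""Tabular readers/writers, packaged fixtures, and the analysis pipeline.

CSV dialect is fixed: comma separator, period decimal, UTF-8, header
mandatory.  ``"ND"`` and the empty cell are the only missing-value
markers, and both mean "not detected" (never zero).

Reports are JSON with values rounded to 6 significant figures and a
provenance block (input SHA-256 checksums, options, seed, package and
generator versions) so a rerun with identical configuration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bioassay import DoseResponseSeries, ScavengingSeries, viability_percent
from .doe import DesignMatrix, DesignPoint, FactorSpec, validate_coded_levels
from .exceptions import ComputationError, DesignError, ValidationError
from .pigment import StabilityMeasurement
from .rsm import (
    TERM_NAMES,
    anova,
    fit_quadratic,
    maximize_over_cube,
    stationary_point,
    validate_model,
)

__all__ = [
    "read_design_csv",
    "write_design_csv",
    "read_stability_csv",
    "read_dose_response_csv",
    "read_dpph_csv",
    "read_factors_json",
    "load_bbd_fixture",
    "load_stability_fixture",
    "fixture_path",
    "RunConfig",
    "run_pipeline",
    "round_sig",
]

_CODED_COLS = ("x1_coded", "x2_coded", "x3_coded")


def round_sig(x: float, digits: int = 6) -> float:
    """Round to ``digits`` significant figures (report precision)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def fixture_path(name: str) -> Path:
    """Path to a packaged data fixture."""
    return Path(str(resources.files("carotlab.data") / name))


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    try:
        return pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = int(coerced.isna().idxmax())
        raise ValidationError(
            f"{path}: malformed numeric cell in column {col!r}, row {bad + 2} "
            f"(value {df[col].iloc[bad]!r})"
        ) from exc


def _factors_from_table(
    df: pd.DataFrame, coded: np.ndarray, path
) -> tuple[FactorSpec, FactorSpec, FactorSpec]:
    actual_cols = [c for c in df.columns if c.endswith("_actual")]
    if len(actual_cols) != 3:
        # coded-only table: identity mapping factors
        return tuple(
            FactorSpec(name=f"x{i + 1}", low=-1.0, center=0.0, high=1.0)
            for i in range(3)
        )
    factors = []
    for i, col in enumerate(actual_cols):
        vals = _numeric(df, col, path)
        levels = {}
        for lv in (-1.0, 0.0, 1.0):
            at = vals[coded[:, i] == lv]
            if len(at) == 0:
                raise DesignError(f"{path}: no runs at coded level {lv} for {col}")
            if np.ptp(at) > 1e-9 * max(1.0, np.abs(at).max()):
                raise DesignError(
                    f"{path}: inconsistent actual values for {col} at coded {lv}"
                )
            levels[lv] = float(at[0])
        factors.append(
            FactorSpec(
                name=col[: -len("_actual")],
                low=levels[-1.0],
                center=levels[0.0],
                high=levels[1.0],
                asymmetric=True,
            )
        )
    return tuple(factors)


def read_design_csv(
    path: str | Path, strict: bool = True
) -> tuple[DesignMatrix, np.ndarray | None]:
    """Read a coded (and optionally actual) design table with response.

    Expected columns: ``run``, ``x1_coded..x3_coded``, optional
    ``<factor>_actual`` triplet and optional ``response``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"design file not found: {path}")
    df = pd.read_csv(path)
    _require_columns(df, ("run", *_CODED_COLS), path)
    coded = np.column_stack([_numeric(df, c, path) for c in _CODED_COLS])
    validate_coded_levels(coded, strict=strict)
    factors = _factors_from_table(df, coded, path)
    runs = _numeric(df, "run", path).astype(int)
    from .doe import code_to_actual

    points = tuple(
        DesignPoint(
            run_id=int(r),
            coded=tuple(row),
            actual=tuple(code_to_actual(c, f) for c, f in zip(row, factors)),
        )
        for r, row in zip(runs, coded)
    )
    n_center = int(np.sum(np.all(coded == 0.0, axis=1)))
    design = DesignMatrix(factors=factors, points=points, n_center=n_center)
    response = None
    if "response" in df.columns:
        response = _numeric(df, "response", path)
    return design, response


def write_design_csv(
    design: DesignMatrix, response: Sequence[float] | None, path: str | Path
) -> None:
    """Write a design (coded + actual columns) and optional response."""
    df = design.to_frame()
    if response is not None:
        if len(response) != design.n_runs:
            raise ValidationError("response length does not match design")
        df["response"] = np.asarray(response, dtype=float)
    df.to_csv(path, index=False)


def read_stability_csv(path: str | Path) -> list[StabilityMeasurement]:
    """Read ``condition,replicate,c0,ct`` rows; blank/"ND" ct = not detected."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"condition": str})
    _require_columns(df, ("condition", "c0", "ct"), path)
    out = []
    for i, row in df.iterrows():
        raw = row["ct"]
        nd = (isinstance(raw, str) and raw.strip().upper() == "ND") or (
            not isinstance(raw, str) and pd.isna(raw)
        )
        if nd:
            ct = None
        else:
            try:
                ct = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: malformed ct value {raw!r} in row {i + 2}"
                ) from exc
        out.append(
            StabilityMeasurement(
                condition=str(row["condition"]), c0=float(row["c0"]), ct=ct
            )
        )
    return out


def read_dose_response_csv(path: str | Path) -> list[DoseResponseSeries]:
    """Read MTT wells and average replicates into per-line viability series.

    Columns: ``agent,cell_line,dose,replicate,absorbance_treated,
    absorbance_control``.  Duplicate wells at the same dose are averaged
    before the viability ratio is formed.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df,
        ("agent", "cell_line", "dose", "absorbance_treated", "absorbance_control"),
        path,
    )
    series = []
    for (agent, line), grp in df.groupby(["agent", "cell_line"], sort=True):
        per_dose = grp.groupby("dose", sort=True)[
            ["absorbance_treated", "absorbance_control"]
        ].mean()
        doses = tuple(float(d) for d in per_dose.index)
        viab = tuple(
            viability_percent(t, c)
            for t, c in zip(
                per_dose["absorbance_treated"], per_dose["absorbance_control"]
            )
        )
        series.append(
            DoseResponseSeries(
                agent=str(agent), cell_line=str(line), doses=doses, viability_pct=viab
            )
        )
    return series


def read_dpph_csv(path: str | Path) -> list[ScavengingSeries]:
    """Read ``concentration,time_min,a_control,a_sample`` rows into series."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("concentration", "time_min", "a_control", "a_sample"), path)
    out = []
    for conc, grp in df.groupby("concentration", sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            ScavengingSeries(
                concentration=float(conc),
                time_min=tuple(grp["time_min"].astype(float)),
                a_control=tuple(grp["a_control"].astype(float)),
                a_sample=tuple(grp["a_sample"].astype(float)),
            )
        )
    return out


def read_factors_json(path: str | Path) -> tuple[FactorSpec, ...]:
    """Read a JSON list of {name, low, center, high, units} factor specs."""
    raw = json.loads(Path(path).read_text())
    return tuple(
        FactorSpec(
            name=d["name"],
            low=float(d["low"]),
            center=float(d["center"]),
            high=float(d["high"]),
            units=d.get("units", ""),
            asymmetric=bool(d.get("asymmetric", False)),
        )
        for d in raw
    )


def load_bbd_fixture() -> tuple[DesignMatrix, np.ndarray]:
    """The packaged 15-run whey/peptone/casein design with measured yields."""
    design, response = read_design_csv(fixture_path("bbd_design.csv"))
    assert response is not None
    return design, response


def load_stability_fixture() -> list[StabilityMeasurement]:
    """The packaged per-condition stability table (residual fractions)."""
    return read_stability_csv(fixture_path("stability_conditions.csv"))


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class RunConfig:
    """Configuration for :func:`run_pipeline`."""

    design_path: str | Path
    out_dir: str | Path
    stages: tuple[str, ...] = ("fit", "anova", "optimize", "validate")
    optimize_mode: str = "cube"  # "cube" | "stationary"
    alpha: float = 0.05
    experimental_value: float | None = None  # for the validate stage
    seed: int = 0

    def __post_init__(self) -> None:
        known = {"fit", "anova", "optimize", "validate"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
        if self.optimize_mode not in ("cube", "stationary"):
            raise ValidationError(f"unknown optimize mode {self.optimize_mode!r}")


def _jsonable(x):
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (np.floating, float)):
        return round_sig(float(x))
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    return x


def _write_report(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the requested stages in dependency order.

    ``fit`` → ``anova``/``optimize``/``validate`` all require the design
    fit, which is computed once.  Each report embeds the input checksum
    and the options used; reruns with identical config are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = tuple(dict.fromkeys(config.stages))  # dedupe, keep order
    written: dict[str, Path] = {}
    if not stages:
        import warnings

        warnings.warn("empty stage list: nothing to do", stacklevel=2)
        return written
    design, response = read_design_csv(config.design_path)
    if response is None:
        raise ValidationError(
            f"{config.design_path}: a 'response' column is required to fit"
        )
    provenance = {
        "carotlab_version": __version__,
        "input": str(config.design_path),
        "input_sha256": sha256_of(config.design_path),
        "seed": config.seed,
        "options": {
            "stages": list(stages),
            "optimize_mode": config.optimize_mode,
            "alpha": config.alpha,
        },
    }
    fit = fit_quadratic(design, response)
    if "fit" in stages:
        table = fit.coefficient_table()
        payload = {
            "provenance": provenance,
            "terms": list(TERM_NAMES),
            "coefficients": {
                row["term"]: {
                    "coefficient": row["coefficient"],
                    "standard_error": row["standard_error"],
                    "t_stat": row["t_stat"],
                    "p_value": row["p_value"],
                    "ci_low_95": row["ci_low_95"],
                    "ci_high_95": row["ci_high_95"],
                }
                for _, row in table.iterrows()
            },
            "df_residual": fit.df_residual,
            "fitted": list(fit.fitted),
            "residuals": list(fit.residuals),
        }
        written["fit"] = out_dir / "fit.json"
        _write_report(payload, written["fit"])
    if "anova" in stages:
        tab = anova(fit, response)
        payload = {
            "provenance": provenance,
            "Regression": {"df": tab.df_reg, "SS": tab.ss_reg, "MS": tab.ms_reg,
                           "F": tab.f_value, "significance_F": tab.significance_f},
            "Residual": {"df": tab.df_res, "SS": tab.ss_res, "MS": tab.ms_res},
            "Total": {"df": tab.df_tot, "SS": tab.ss_tot},
            "r_squared": tab.r_squared,
            "adj_r_squared": tab.adj_r_squared,
        }
        written["anova"] = out_dir / "anova.json"
        _write_report(payload, written["anova"])
    predicted_max = None
    if "optimize" in stages:
        if config.optimize_mode == "cube":
            opt = maximize_over_cube(fit, design.factors)
            predicted_max = opt.predicted_max
            payload = {
                "provenance": provenance,
                "mode": "cube",
                "coded_location": list(opt.coded_location),
                "actual_location": list(opt.actual_location),
                "predicted_max": opt.predicted_max,
                "on_boundary": list(opt.on_boundary),
            }
        else:
            sp = stationary_point(fit, design.factors)
            predicted_max = sp.predicted_response
            payload = {
                "provenance": provenance,
                "mode": "stationary",
                "coded_location": list(sp.coded_location),
                "actual_location": list(sp.actual_location),
                "predicted_response": sp.predicted_response,
                "nature": sp.nature,
                "eigenvalues": list(sp.eigenvalues),
            }
        written["optimize"] = out_dir / "optimum.json"
        _write_report(payload, written["optimize"])
    if "validate" in stages:
        if config.experimental_value is None:
            raise ValidationError(
                "validate stage requires experimental_value in the RunConfig"
            )
        if predicted_max is None:
            opt = maximize_over_cube(fit, design.factors)
            predicted_max = opt.predicted_max
        vr = validate_model(predicted_max, config.experimental_value)
        payload = {
            "provenance": provenance,
            "predicted": vr.predicted,
            "experimental": vr.experimental,
            "accuracy_pct": vr.accuracy_pct,
            "deviation_pct": vr.deviation_pct,
        }
        written["validate"] = out_dir / "validation.json"
        _write_report(payload, written["validate"])
    return written
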