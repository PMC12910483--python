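"""Second-order response-surface fitting, ANOVA, and optimum extraction.

The response model is the full second-order polynomial in three coded
factors,

    Y = b0 + b1*X1 + b2*X2 + b3*X3
        + b12*X1*X2 + b13*X1*X3 + b23*X2*X3
        + b11*X1**2 + b22*X2**2 + b33*X3**2,

fit by ordinary least squares on the coded model matrix.  Inference uses
the t distribution with ``n - 10`` residual degrees of freedom; the ANOVA
decomposes total (mean-corrected) sum of squares into regression and
residual parts and reports the model F statistic.

The fitted surface can be interrogated three ways: the analytic
stationary point (canonical analysis via the eigenvalues of the
quadratic-form matrix), a deterministic constrained maximum over the
coded cube ``[-1, 1]^3`` (lattice scan plus local refinement), and slice
grids for surface plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .doe import DesignMatrix, FactorSpec, code_to_actual
from .exceptions import (
    ComputationError,
    DomainError,
    InsufficientDataError,
    RankDeficiencyError,
    ValidationError,
)

__all__ = [
    "TERM_NAMES",
    "QuadraticSurface",
    "QuadraticFit",
    "AnovaTable",
    "StationaryPoint",
    "CubeOptimum",
    "ValidationResult",
    "quadratic_terms",
    "fit_quadratic",
    "anova",
    "predict",
    "stationary_point",
    "maximize_over_cube",
    "validate_model",
    "surface_grid",
    "compare_groups",
]

#: Model terms in canonical order (10 coefficients).
TERM_NAMES = (
    "Intercept",
    "X1",
    "X2",
    "X3",
    "X1X2",
    "X1X3",
    "X2X3",
    "X1X1",
    "X2X2",
    "X3X3",
)

N_TERMS = 10


def quadratic_terms(coded: np.ndarray) -> np.ndarray:
    """Expand (n, 3) coded settings into the (n, 10) model matrix."""
    X = np.atleast_2d(np.asarray(coded, dtype=float))
    if X.shape[1] != 3:
        raise ValidationError(f"expected 3 coded columns, got {X.shape[1]}")
    x1, x2, x3 = X[:, 0], X[:, 1], X[:, 2]
    return np.column_stack(
        [np.ones(len(X)), x1, x2, x3, x1 * x2, x1 * x3, x2 * x3, x1**2, x2**2, x3**2]
    )


class QuadraticSurface(RegressorMixin, BaseEstimator):
    """Full second-order polynomial regressor on three coded factors.

    Scikit-learn style estimator: ``fit(X, y)`` with ``X`` the (n, 3)
    coded design and ``y`` the response (e.g. pigment yield in mg/mL),
    ``predict(X)`` evaluating the fitted 10-term polynomial.

    Parameters
    ----------
    conf_level : float
        Two-sided confidence level for the coefficient intervals.

    Attributes
    ----------
    coef_ : ndarray of shape (10,)
        Coefficients in :data:`TERM_NAMES` order (intercept first).
    se_, t_, p_, ci_low_, ci_high_ : ndarray of shape (10,)
        Standard errors, t statistics, two-sided p-values and confidence
        bounds from the t distribution with ``df_residual_`` df.
    fitted_, residuals_ : ndarray of shape (n,)
    df_residual_ : int
    """

    def __init__(self, conf_level: float = 0.95):
        self.conf_level = conf_level

    def fit(self, X, y):
        if isinstance(X, DesignMatrix):
            X = X.coded()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        M = quadratic_terms(X)
        n = M.shape[0]
        if len(y) != n:
            raise ValidationError(
                f"response length {len(y)} does not match {n} design runs"
            )
        if not np.all(np.isfinite(y)):
            raise ValidationError("response contains non-finite values")
        if np.any(y < 0):
            warnings.warn("response contains negative values", stacklevel=2)
        if n < N_TERMS + 1:
            raise InsufficientDataError(
                f"need at least {N_TERMS + 1} runs to fit {N_TERMS} coefficients "
                f"with a residual df, got {n}"
            )
        rank = np.linalg.matrix_rank(M)
        if rank < N_TERMS:
            # name the columns involved in the deficiency via QR pivoting
            _, _, piv = _qr_pivot(M)
            dependent = [TERM_NAMES[j] for j in piv[rank:]]
            raise RankDeficiencyError(
                f"model matrix is rank deficient (rank {rank} < {N_TERMS}); "
                f"dependent columns: {', '.join(dependent)}",
                columns=dependent,
            )
        xtx_inv = np.linalg.inv(M.T @ M)
        beta = xtx_inv @ (M.T @ y)
        fitted = M @ beta
        resid = y - fitted
        df_res = n - N_TERMS
        ms_res = float(resid @ resid) / df_res
        se = np.sqrt(ms_res * np.diag(xtx_inv))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se  # inf/nan under a perfect (zero-residual) fit
        pval = 2.0 * stats.t.sf(np.abs(tstat), df_res)
        tq = stats.t.ppf(0.5 + self.conf_level / 2.0, df_res)
        self.coef_ = beta
        self.se_ = se
        self.t_ = tstat
        self.p_ = pval
        self.ci_low_ = beta - tq * se
        self.ci_high_ = beta + tq * se
        self.fitted_ = fitted
        self.residuals_ = resid
        self.df_residual_ = df_res
        self.ms_residual_ = ms_res
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        if isinstance(X, DesignMatrix):
            X = X.coded()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.any(np.abs(X) > 1.0):
            warnings.warn(
                "predicting outside the coded cube [-1, 1]^3 (extrapolation)",
                stacklevel=2,
            )
        return quadratic_terms(X) @ self.coef_


def _qr_pivot(M: np.ndarray):
    from scipy.linalg import qr

    return qr(M, pivoting=True)


@dataclass(frozen=True)
class QuadraticFit:
    """Coefficients and inference of the fitted second-order model."""

    beta0: float
    beta_lin: tuple[float, float, float]
    beta_cross: tuple[float, float, float]
    beta_quad: tuple[float, float, float]
    se: tuple[float, ...]
    t_stat: tuple[float, ...]
    p_value: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]
    fitted: tuple[float, ...]
    residuals: tuple[float, ...]
    df_residual: int

    @property
    def beta(self) -> np.ndarray:
        """All 10 coefficients in :data:`TERM_NAMES` order."""
        return np.array(
            (self.beta0, *self.beta_lin, *self.beta_cross, *self.beta_quad)
        )

    def coefficient_table(self) -> pd.DataFrame:
        """Report mirroring the usual regression output columns."""
        return pd.DataFrame(
            {
                "term": TERM_NAMES,
                "coefficient": self.beta,
                "standard_error": self.se,
                "t_stat": self.t_stat,
                "p_value": self.p_value,
                "ci_low_95": self.ci_low,
                "ci_high_95": self.ci_high,
            }
        )


@dataclass(frozen=True)
class AnovaTable:
    """Regression/residual/total decomposition of the model fit."""

    df_reg: int
    df_res: int
    df_tot: int
    ss_reg: float
    ss_res: float
    ss_tot: float
    ms_reg: float
    ms_res: float
    f_value: float
    significance_f: float
    r_squared: float
    adj_r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["Regression", "Residual", "Total"],
                "df": [self.df_reg, self.df_res, self.df_tot],
                "SS": [self.ss_reg, self.ss_res, self.ss_tot],
                "MS": [self.ms_reg, self.ms_res, np.nan],
                "F": [self.f_value, np.nan, np.nan],
                "significance_F": [self.significance_f, np.nan, np.nan],
            }
        )


@dataclass(frozen=True)
class StationaryPoint:
    coded_location: tuple[float, float, float]
    actual_location: tuple[float, float, float]
    predicted_response: float
    nature: str  # "maximum" | "minimum" | "saddle"
    eigenvalues: tuple[float, float, float]


@dataclass(frozen=True)
class CubeOptimum:
    coded_location: tuple[float, float, float]
    actual_location: tuple[float, float, float]
    predicted_max: float
    on_boundary: tuple[bool, bool, bool]


@dataclass(frozen=True)
class ValidationResult:
    predicted: float
    experimental: float
    accuracy_pct: float
    deviation_pct: float


def _estimator_to_fit(est: QuadraticSurface) -> QuadraticFit:
    b = est.coef_
    return QuadraticFit(
        beta0=float(b[0]),
        beta_lin=tuple(b[1:4]),
        beta_cross=tuple(b[4:7]),
        beta_quad=tuple(b[7:10]),
        se=tuple(est.se_),
        t_stat=tuple(est.t_),
        p_value=tuple(est.p_),
        ci_low=tuple(est.ci_low_),
        ci_high=tuple(est.ci_high_),
        fitted=tuple(est.fitted_),
        residuals=tuple(est.residuals_),
        df_residual=est.df_residual_,
    )


def fit_quadratic(design: DesignMatrix | np.ndarray, response) -> QuadraticFit:
    """OLS fit of the full second-order model on the coded design.

    Thin wrapper over :class:`QuadraticSurface`.
    """
    est = QuadraticSurface().fit(design, response)
    return _estimator_to_fit(est)


def anova(fit: QuadraticFit, response) -> AnovaTable:
    """ANOVA decomposition of a :class:`QuadraticFit` against its response."""
    y = np.asarray(response, dtype=float).ravel()
    fitted = np.asarray(fit.fitted)
    if len(y) != len(fitted):
        raise ValidationError(
            f"response length {len(y)} does not match fit ({len(fitted)} runs)"
        )
    if not np.allclose(fitted + np.asarray(fit.residuals), y, rtol=1e-9, atol=1e-12):
        raise ValidationError("response does not match the one used for the fit")
    resid = np.asarray(fit.residuals)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(resid @ resid)
    ss_reg = ss_tot - ss_res
    n = len(y)
    df_reg = N_TERMS - 1
    df_res = fit.df_residual
    ms_reg = ss_reg / df_reg
    ms_res = ss_res / df_res
    if ms_res > 0:
        f_value = ms_reg / ms_res
        sig_f = float(stats.f.sf(f_value, df_reg, df_res))
    else:  # perfect fit
        f_value = np.inf
        sig_f = 0.0
    r2 = ss_reg / ss_tot if ss_tot > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_res if ss_tot > 0 else np.nan
    return AnovaTable(
        df_reg=df_reg,
        df_res=df_res,
        df_tot=n - 1,
        ss_reg=ss_reg,
        ss_res=ss_res,
        ss_tot=ss_tot,
        ms_reg=ms_reg,
        ms_res=ms_res,
        f_value=float(f_value),
        significance_f=sig_f,
        r_squared=float(r2),
        adj_r_squared=float(adj_r2),
    )


def predict(fit: QuadraticFit, coded) -> float | np.ndarray:
    """Evaluate the fitted 10-term polynomial at coded settings.

    Accepts a single (3,) point or an (n, 3) array; warns on
    extrapolation outside the coded cube.
    """
    arr = np.asarray(coded, dtype=float)
    single = arr.ndim == 1
    if np.any(np.abs(arr) > 1.0):
        warnings.warn(
            "predicting outside the coded cube [-1, 1]^3 (extrapolation)",
            stacklevel=2,
        )
    out = quadratic_terms(np.atleast_2d(arr)) @ fit.beta
    return float(out[0]) if single else out


def _quad_form(fit: QuadraticFit) -> tuple[np.ndarray, np.ndarray]:
    """Gradient vector b and symmetric quadratic-form matrix B of the surface."""
    b = np.asarray(fit.beta_lin)
    b12, b13, b23 = fit.beta_cross
    b11, b22, b33 = fit.beta_quad
    B = np.array(
        [
            [b11, b12 / 2.0, b13 / 2.0],
            [b12 / 2.0, b22, b23 / 2.0],
            [b13 / 2.0, b23 / 2.0, b33],
        ]
    )
    return b, B


def stationary_point(
    fit: QuadraticFit, factors: Sequence[FactorSpec]
) -> StationaryPoint:
    """Canonical analysis: solve grad Y = b + 2 B x = 0 and classify.

    The nature of the stationary point follows the eigenvalues of the
    quadratic-form matrix B: all negative -> maximum, all positive ->
    minimum, mixed signs -> saddle.
    """
    b, B = _quad_form(fit)
    if abs(np.linalg.det(B)) < 1e-14:
        raise ComputationError(
            "quadratic-form matrix is singular (degenerate surface); "
            "use maximize_over_cube instead"
        )
    x = np.linalg.solve(2.0 * B, -b)
    eig = np.sort(np.linalg.eigvalsh(B))
    if np.all(eig < 0):
        nature = "maximum"
    elif np.all(eig > 0):
        nature = "minimum"
    else:
        nature = "saddle"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = predict(fit, x)
    actual = tuple(code_to_actual(float(c), f) for c, f in zip(x, factors))
    return StationaryPoint(
        coded_location=tuple(float(v) for v in x),
        actual_location=actual,
        predicted_response=float(pred),
        nature=nature,
        eigenvalues=tuple(float(v) for v in eig),
    )


def maximize_over_cube(
    fit: QuadraticFit,
    factors: Sequence[FactorSpec],
    lattice_step: float = 0.01,
) -> CubeOptimum:
    """Deterministic global maximum of the fitted quadratic over [-1, 1]^3.

    Exhaustive scan of a ``lattice_step``-spaced lattice followed by
    bounded local refinement (L-BFGS-B) from the best lattice point.
    Lattice ties break to the lexicographically smallest coded
    coordinates; flat directions stay at the tie-broken start.
    """
    beta = fit.beta
    n_ax = int(round(2.0 / lattice_step)) + 1
    ax = np.linspace(-1.0, 1.0, n_ax)
    X1, X2, X3 = np.meshgrid(ax, ax, ax, indexing="ij")
    Y = (
        beta[0]
        + beta[1] * X1
        + beta[2] * X2
        + beta[3] * X3
        + beta[4] * X1 * X2
        + beta[5] * X1 * X3
        + beta[6] * X2 * X3
        + beta[7] * X1**2
        + beta[8] * X2**2
        + beta[9] * X3**2
    )
    # first occurrence in C order = lexicographically smallest (x1, x2, x3)
    idx = np.unravel_index(int(np.argmax(Y)), Y.shape)
    x0 = np.array([ax[idx[0]], ax[idx[1]], ax[idx[2]]])
    b_lin, B = _quad_form(fit)
    res = optimize.minimize(
        lambda x: -float((quadratic_terms(x[None, :]) @ beta)[0]),
        x0,
        jac=lambda x: -(b_lin + 2.0 * B @ x),
        bounds=[(-1.0, 1.0)] * 3,
        method="L-BFGS-B",
        options={"ftol": 1e-16, "gtol": 1e-12},
    )
    x = np.clip(res.x, -1.0, 1.0)
    best = float((quadratic_terms(x[None, :]) @ beta)[0])
    lattice_best = float(Y[idx])
    if best < lattice_best:  # refinement must never lose to the lattice
        x, best = x0, lattice_best
    actual = tuple(code_to_actual(float(c), f) for c, f in zip(x, factors))
    return CubeOptimum(
        coded_location=tuple(float(v) for v in x),
        actual_location=actual,
        predicted_max=best,
        on_boundary=tuple(bool(abs(v) > 1.0 - 1e-9) for v in x),
    )


def validate_model(predicted: float, experimental: float) -> ValidationResult:
    """Accuracy and deviation of an experimental verification run.

    accuracy% = 100 * experimental / predicted;
    deviation% = 100 * |predicted - experimental| / predicted.
    """
    if predicted <= 0:
        raise DomainError(f"predicted value must be positive, got {predicted}")
    return ValidationResult(
        predicted=predicted,
        experimental=experimental,
        accuracy_pct=100.0 * experimental / predicted,
        deviation_pct=100.0 * abs(predicted - experimental) / predicted,
    )


def surface_grid(
    fit: QuadraticFit,
    pair: tuple[int, int],
    fixed: float = 0.0,
    resolution: int = 41,
) -> pd.DataFrame:
    """Predicted-response grid over a coded [-1, 1]^2 slice for plotting.

    ``pair`` gives the two varying factor indices (0-based); the third
    factor is held at ``fixed``.
    """
    if resolution < 2:
        raise ValidationError(f"resolution must be >= 2, got {resolution}")
    i, j = pair
    if i == j or not {i, j} <= {0, 1, 2}:
        raise ValidationError(f"pair must be two distinct indices in 0..2, got {pair}")
    k = 3 - i - j
    ax = np.linspace(-1.0, 1.0, resolution)
    gi, gj = np.meshgrid(ax, ax, indexing="ij")
    pts = np.zeros((resolution * resolution, 3))
    pts[:, i] = gi.ravel()
    pts[:, j] = gj.ravel()
    pts[:, k] = fixed
    pred = quadratic_terms(pts) @ fit.beta
    return pd.DataFrame(
        {
            f"x{i + 1}_coded": pts[:, i],
            f"x{j + 1}_coded": pts[:, j],
            f"x{k + 1}_fixed": pts[:, k],
            "predicted": pred,
        }
    )


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    control: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group mean ± SE with Welch pairwise tests against a control.

    Used for one-variable-at-a-time screening summaries (e.g. culture
    volume or medium additive comparisons).  ``control`` defaults to the
    first group in mapping order.
    """
    if len(groups) < 2:
        raise ValidationError("at least 2 groups required")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(
                f"group {label!r} has {len(vals)} value(s); >= 2 replicates required"
            )
    labels = list(groups)
    if control is None:
        control = labels[0]
    if control not in groups:
        raise ValidationError(f"control group {control!r} not found")
    ctrl = np.asarray(groups[control], dtype=float)
    rows = []
    for label in labels:
        vals = np.asarray(groups[label], dtype=float)
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        if label == control:
            p = np.nan
            sig = False
        else:
            p = float(stats.ttest_ind(vals, ctrl, equal_var=False).pvalue)
            sig = p <= alpha
        rows.append(
            {
                "group": label,
                "n": len(vals),
                "mean": mean,
                "se": se,
                "p_vs_control": p,
                "significant": sig,
            }
        )
    return pd.DataFrame(rows)
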