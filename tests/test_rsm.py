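"""Second-order surface fitting, ANOVA, and optimum extraction."""

import numpy as np
import pytest
from scipy import stats

from carotlab.doe import FactorSpec, build_bbd
from carotlab.exceptions import (
    ComputationError,
    DomainError,
    RankDeficiencyError,
    ValidationError,
)
from carotlab.rsm import (
    QuadraticSurface,
    anova,
    compare_groups,
    fit_quadratic,
    maximize_over_cube,
    predict,
    quadratic_terms,
    stationary_point,
    surface_grid,
    validate_model,
)

UNIT_FACTORS = tuple(
    FactorSpec(f"x{i + 1}", -1.0, 0.0, 1.0) for i in range(3)
)

# Published coefficient table of the 15-run whey/peptone/casein fit
# (term: coefficient, SE, t, p, upper 95% bound), printed precision.
PRINTED_COEFFICIENTS = {
    "Intercept": (0.022, 0.004715, 4.666246, 0.005501, 0.03412),
    "X1": (0.006888, 0.002887, 2.385563, 0.062731, 0.014309),
    "X2": (-0.00661, 0.002887, -2.29031, 0.070622, 0.000809),
    "X3": (0.002475, 0.002887, 0.857244, 0.430472, 0.009897),
    "X1X2": (-0.01313, 0.004083, -3.2145, 0.02361, -0.00263),
    "X1X3": (-0.00065, 0.004083, -0.15919, 0.879746, 0.009846),
    "X2X3": (0.00655, 0.004083, 1.604189, 0.169578, 0.017046),
    "X1X1": (0.002463, 0.00425, 0.579441, 0.587417, 0.013387),
    "X2X2": (0.004913, 0.00425, 1.155941, 0.299935, 0.015837),
    "X3X3": (-0.00646, 0.00425, -1.52067, 0.188823, 0.004462),
}


def _printed_tol(printed: float) -> float:
    """Half a unit in the last printed decimal place."""
    text = f"{printed}"
    decimals = len(text.split(".")[1]) if "." in text else 0
    return 0.5 * 10.0**-decimals + 1e-12


class TestQuadraticFit:
    def test_reproduces_published_coefficient_table(self, bbd_fit):
        table = bbd_fit.coefficient_table().set_index("term")
        for term, (coef, se, t, p, hi) in PRINTED_COEFFICIENTS.items():
            row = table.loc[term]
            assert row["coefficient"] == pytest.approx(coef, abs=_printed_tol(coef))
            assert row["standard_error"] == pytest.approx(se, abs=_printed_tol(se))
            assert row["t_stat"] == pytest.approx(t, abs=_printed_tol(t))
            assert row["p_value"] == pytest.approx(p, abs=_printed_tol(p))
            assert row["ci_high_95"] == pytest.approx(hi, abs=_printed_tol(hi))

    def test_matches_pseudoinverse_oracle(self, bbd_design_response):
        design, y = bbd_design_response
        M = quadratic_terms(design.coded())
        beta_oracle = np.linalg.pinv(M) @ y
        fit = fit_quadratic(design, y)
        assert fit.beta == pytest.approx(beta_oracle, abs=1e-10)

    def test_matches_statsmodels_oracle(self, bbd_design_response):
        sm = pytest.importorskip("statsmodels.api")
        design, y = bbd_design_response
        M = quadratic_terms(design.coded())
        res = sm.OLS(y, M).fit()
        fit = fit_quadratic(design, y)
        assert fit.beta == pytest.approx(res.params, abs=1e-12)
        assert np.asarray(fit.se) == pytest.approx(res.bse, abs=1e-12)
        assert np.asarray(fit.p_value) == pytest.approx(res.pvalues, abs=1e-12)

    def test_orthogonality_contrast_shortcut(self, bbd_design_response):
        # for the 15-run BBD, each linear coefficient is the ±1-level
        # contrast over 8 and each interaction the (±1, ±1) contrast over 4
        design, y = bbd_design_response
        coded = design.coded()
        fit = fit_quadratic(design, y)
        for i in range(3):
            contrast = (y[coded[:, i] == 1].sum() - y[coded[:, i] == -1].sum()) / 8.0
            assert fit.beta_lin[i] == pytest.approx(contrast, abs=1e-12)
        for idx, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
            prod = coded[:, i] * coded[:, j]
            contrast = (y[prod == 1].sum() - y[prod == -1].sum()) / 4.0
            assert fit.beta_cross[idx] == pytest.approx(contrast, abs=1e-12)

    def test_noiseless_surface_recovered_exactly(self, rng):
        design = build_bbd(UNIT_FACTORS, n_center=3)
        truth = rng.normal(0, 1, size=10)
        y = quadratic_terms(design.coded()) @ truth
        fit = fit_quadratic(design, y)
        assert fit.beta == pytest.approx(truth, abs=1e-10)
        assert np.asarray(fit.residuals) == pytest.approx(0.0, abs=1e-12)

    def test_fitted_plus_residuals_is_response(self, bbd_design_response, bbd_fit):
        _, y = bbd_design_response
        recon = np.asarray(bbd_fit.fitted) + np.asarray(bbd_fit.residuals)
        assert recon == pytest.approx(y, abs=1e-14)
        assert bbd_fit.df_residual == 5
        assert float(np.sum(bbd_fit.residuals)) == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_names_dependent_columns(self):
        coded = np.zeros((15, 3))
        coded[:, 0] = np.tile([-1.0, 0.0, 1.0], 5)  # x2, x3 constant
        with pytest.raises(RankDeficiencyError):
            QuadraticSurface().fit(coded, np.arange(15.0))

    def test_length_mismatch_is_alignment_error(self, bbd_design_response):
        design, y = bbd_design_response
        with pytest.raises(ValidationError, match="length"):
            fit_quadratic(design, y[:-1])


class TestAnova:
    def test_reproduces_published_decomposition(self, bbd_design_response, bbd_fit):
        _, y = bbd_design_response
        tab = anova(bbd_fit, y)
        assert (tab.df_reg, tab.df_res, tab.df_tot) == (9, 5, 14)
        assert tab.ss_reg == pytest.approx(0.001928, abs=5e-7)
        assert tab.ss_res == pytest.approx(0.000333, abs=5e-7)
        assert tab.ms_res == pytest.approx(6.67e-05, abs=5e-8)
        assert tab.f_value == pytest.approx(3.21, abs=5e-3)
        assert tab.significance_f == pytest.approx(0.105, abs=1e-3)
        assert tab.ss_tot == pytest.approx(0.002262, abs=5e-7)
        assert tab.r_squared == pytest.approx(0.85, abs=5e-3)

    def test_sum_of_squares_identity_on_random_data(self, rng):
        design = build_bbd(UNIT_FACTORS, n_center=3)
        for _ in range(20):
            y = rng.normal(0, 1, size=15)
            fit = fit_quadratic(design, y)
            tab = anova(fit, y)
            assert tab.ss_reg + tab.ss_res == pytest.approx(
                tab.ss_tot, rel=1e-12, abs=1e-15
            )
            assert tab.r_squared == pytest.approx(tab.ss_reg / tab.ss_tot, rel=1e-12)
            assert tab.f_value == pytest.approx(tab.ms_reg / tab.ms_res, rel=1e-12)

    def test_perfect_fit_gives_unit_r_squared(self, rng):
        design = build_bbd(UNIT_FACTORS, n_center=3)
        y = quadratic_terms(design.coded()) @ rng.normal(0, 1, size=10)
        fit = fit_quadratic(design, y)
        tab = anova(fit, y)
        assert tab.ss_res == pytest.approx(0.0, abs=1e-20)
        assert tab.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_response_rejected(self, bbd_design_response, bbd_fit):
        _, y = bbd_design_response
        with pytest.raises(ValidationError):
            anova(bbd_fit, y + 0.01)


class TestPredict:
    def test_reproduces_published_fitted_column(self, bbd_design_response, bbd_fit):
        design, _ = bbd_design_response
        pred = predict(bbd_fit, design.coded())
        assert pred == pytest.approx(np.asarray(bbd_fit.fitted), abs=1e-12)

    def test_center_prediction_is_intercept(self, bbd_fit):
        assert predict(bbd_fit, [0.0, 0.0, 0.0]) == pytest.approx(bbd_fit.beta0)

    @pytest.mark.parametrize(
        "coded,expected",
        [((1, -1, 0), 0.0560), ((0, -1, 1), 0.0229)],
    )
    def test_published_trial_predictions(self, bbd_fit, coded, expected):
        assert predict(bbd_fit, list(coded)) == pytest.approx(expected, abs=1e-4)

    def test_extrapolation_warns(self, bbd_fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            predict(bbd_fit, [2.0, 0.0, 0.0])


class TestStationaryPoint:
    def _fit_from_beta(self, beta):
        design = build_bbd(UNIT_FACTORS, n_center=3)
        y = quadratic_terms(design.coded()) @ np.asarray(beta, dtype=float)
        return fit_quadratic(design, y)

    def test_symmetric_bowl_is_maximum_at_origin(self):
        fit = self._fit_from_beta([1, 0, 0, 0, 0, 0, 0, -1, -1, -1])
        sp = stationary_point(fit, UNIT_FACTORS)
        assert sp.nature == "maximum"
        assert sp.coded_location == pytest.approx((0, 0, 0), abs=1e-9)
        assert sp.predicted_response == pytest.approx(1.0, abs=1e-9)

    def test_sign_flip_gives_minimum(self):
        fit = self._fit_from_beta([0, 0, 0, 0, 0, 0, 0, 1, 1, 1])
        assert stationary_point(fit, UNIT_FACTORS).nature == "minimum"

    def test_study_surface_is_saddle(self, bbd_fit, study_factors):
        # mixed-sign pure-quadratic terms force mixed eigenvalues
        sp = stationary_point(bbd_fit, study_factors)
        assert sp.nature == "saddle"
        eig = np.asarray(sp.eigenvalues)
        assert eig.min() < 0 < eig.max()
        # independent eigendecomposition oracle on the quadratic-form matrix
        b12, b13, b23 = bbd_fit.beta_cross
        b11, b22, b33 = bbd_fit.beta_quad
        B = np.array([[b11, b12 / 2, b13 / 2], [b12 / 2, b22, b23 / 2],
                      [b13 / 2, b23 / 2, b33]])
        assert eig == pytest.approx(np.sort(np.linalg.eigvalsh(B)), abs=1e-12)

    def test_gradient_vanishes_at_stationary_point(self, bbd_fit, study_factors):
        sp = stationary_point(bbd_fit, study_factors)
        x = np.asarray(sp.coded_location)
        h = 1e-7
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            g = (predict(bbd_fit, x + e) - predict(bbd_fit, x - e)) / (2 * h)
            assert g == pytest.approx(0.0, abs=1e-7)

    def test_degenerate_surface_raises(self):
        fit = self._fit_from_beta([0, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ComputationError, match="singular"):
            stationary_point(fit, UNIT_FACTORS)


class TestMaximizeOverCube:
    def test_study_surface_optimum(self, bbd_fit, study_factors):
        # frozen from an independent 401-point-per-axis brute-force scan
        opt = maximize_over_cube(bbd_fit, study_factors)
        assert opt.coded_location[0] == pytest.approx(1.0)
        assert opt.coded_location[1] == pytest.approx(-1.0)
        assert opt.coded_location[2] == pytest.approx(-0.36557, abs=1e-4)
        assert opt.predicted_max == pytest.approx(0.0568637, abs=1e-6)
        assert opt.on_boundary == (True, True, False)
        assert opt.actual_location[0] == pytest.approx(80.0)
        assert opt.actual_location[1] == pytest.approx(0.5)

    def test_dominates_every_lattice_vertex(self, bbd_fit, study_factors):
        opt = maximize_over_cube(bbd_fit, study_factors)
        ax = np.linspace(-1, 1, 101)
        g = np.array(np.meshgrid(ax, ax, ax, indexing="ij")).reshape(3, -1).T
        vals = quadratic_terms(g) @ bbd_fit.beta
        assert opt.predicted_max >= vals.max() - 1e-12

    def test_linear_surface_tie_breaks_lexicographically(self):
        design = build_bbd(UNIT_FACTORS, n_center=3)
        y = design.coded()[:, 0]  # Y = x1
        fit = fit_quadratic(design, y)
        opt = maximize_over_cube(fit, UNIT_FACTORS)
        assert opt.coded_location == pytest.approx((1.0, -1.0, -1.0))
        assert opt.predicted_max == pytest.approx(1.0, abs=1e-9)

    def test_interior_optimum_matches_stationary_point(self):
        # concave bowl centered at (0.2, 0.2, 0.2)
        design = build_bbd(UNIT_FACTORS, n_center=3)
        c = 0.2
        coded = design.coded()
        y = 1.0 - ((coded - c) ** 2).sum(axis=1)
        fit = fit_quadratic(design, y)
        opt = maximize_over_cube(fit, UNIT_FACTORS)
        sp = stationary_point(fit, UNIT_FACTORS)
        assert sp.nature == "maximum"
        assert opt.coded_location == pytest.approx(sp.coded_location, abs=1e-6)
        assert opt.predicted_max == pytest.approx(sp.predicted_response, abs=1e-9)
        assert opt.on_boundary == (False, False, False)


class TestValidateModel:
    def test_published_verification_run(self):
        vr = validate_model(0.0565, 0.0453)
        assert vr.accuracy_pct == pytest.approx(80.2, abs=0.05)
        assert vr.accuracy_pct + vr.deviation_pct == pytest.approx(100.0)

    def test_exact_agreement(self):
        vr = validate_model(0.05, 0.05)
        assert vr.accuracy_pct == 100.0
        assert vr.deviation_pct == 0.0

    def test_half_prediction(self):
        assert validate_model(0.056, 0.028).accuracy_pct == pytest.approx(50.0)

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(DomainError):
            validate_model(0.0, 0.01)


class TestSurfaceGrid:
    def test_bowl_center_row_is_intercept(self):
        design = build_bbd(UNIT_FACTORS, n_center=3)
        beta = np.array([2.0, 0, 0, 0, 0, 0, 0, -1, -1, -1])
        y = quadratic_terms(design.coded()) @ beta
        fit = fit_quadratic(design, y)
        grid = surface_grid(fit, (0, 1), fixed=0.0, resolution=3)
        assert len(grid) == 9
        center = grid[(grid["x1_coded"] == 0) & (grid["x2_coded"] == 0)]
        assert float(center["predicted"].iloc[0]) == pytest.approx(2.0, abs=1e-9)

    def test_corner_matches_published_trial(self, bbd_fit):
        grid = surface_grid(bbd_fit, (0, 1), fixed=0.0, resolution=3)
        corner = grid[(grid["x1_coded"] == 1) & (grid["x2_coded"] == -1)]
        assert float(corner["predicted"].iloc[0]) == pytest.approx(0.0560, abs=1e-4)

    def test_fine_grid_max_converges_to_slice_optimum(self, bbd_fit, study_factors):
        # restrict the cube optimum to the x3 = -0.36557 slice
        opt = maximize_over_cube(bbd_fit, study_factors)
        grid = surface_grid(bbd_fit, (0, 1), fixed=opt.coded_location[2],
                            resolution=201)
        assert grid["predicted"].max() == pytest.approx(opt.predicted_max, abs=1e-6)

    def test_resolution_validated(self, bbd_fit):
        with pytest.raises(ValidationError):
            surface_grid(bbd_fit, (0, 1), resolution=1)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = {"control": [1.0, 1.1, 0.9], "treated": [1.0, 1.1, 0.9]}
        out = compare_groups(g, control="control").set_index("group")
        assert out.loc["treated", "p_vs_control"] == pytest.approx(1.0, abs=1e-9)
        assert not out.loc["treated", "significant"]

    def test_separated_means_flagged(self, rng):
        g = {
            "a": (1.0 + rng.normal(0, 1e-6, 3)).tolist(),
            "b": (2.0 + rng.normal(0, 1e-6, 3)).tolist(),
        }
        out = compare_groups(g, control="a", alpha=0.05).set_index("group")
        assert out.loc["b", "significant"]

    def test_welch_p_matches_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.8, 1.5, 8)
        out = compare_groups({"a": a.tolist(), "b": b.tolist()}, control="a")
        welch_p = float(out.set_index("group").loc["b", "p_vs_control"])

        def statistic(x, y):
            return stats.ttest_ind(x, y, equal_var=False).statistic

        perm = stats.permutation_test(
            (b, a), statistic, n_resamples=10**5, alternative="two-sided",
            rng=np.random.default_rng(7),
        )
        # Monte-Carlo agreement between Welch and permutation references
        assert welch_p == pytest.approx(perm.pvalue, abs=0.02)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValidationError, match="replicates"):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})
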