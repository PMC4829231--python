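import math

import numpy as np
import pytest

from smeedfit import (
    DiagnosticsRecord,
    GeneratorConfig,
    InsufficientDataError,
    SingularFitError,
    TransformedPoint,
    diagnostics,
    fit_ols,
    fit_with_exclusion,
    flag_outliers,
    generate_series,
    transform_series,
)


def points_from_arrays(x, y):
    return [TransformedPoint(x=float(xi), y=float(yi), year=2000 + i) for i, (xi, yi) in enumerate(zip(x, y))]


def normal_equations(x, y):
    """Independent closed-form simple-regression oracle."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    beta1 = np.sum((x - xbar) * (y - ybar)) / sxx
    beta0 = ybar - beta1 * xbar
    return beta0, beta1


def loo_studentized(x, y, i):
    """Externally studentized residual by literally refitting without point i."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = np.arange(len(x)) != i
    b0, b1 = normal_equations(x[mask], y[mask])
    resid = y[mask] - b0 - b1 * x[mask]
    s2 = np.sum(resid**2) / (mask.sum() - 2)
    xb = x[mask].mean()
    sxx = np.sum((x[mask] - xb) ** 2)
    # prediction variance at x_i from the leave-one-out fit
    pred_var = s2 * (1.0 + 1.0 / mask.sum() + (x[i] - xb) ** 2 / sxx)
    return (y[i] - b0 - b1 * x[i]) / math.sqrt(pred_var)


class TestFitOls:
    def test_exact_line(self):
        fit = fit_ols(points_from_arrays([0, 1, 2], [0, 1, 2]))
        assert fit.params.beta0 == pytest.approx(0.0, abs=1e-12)
        assert fit.params.beta1 == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_symmetric_arrangement_zero_slope(self):
        fit = fit_ols(points_from_arrays([0, 1, 2], [0, 1, 0]))
        assert fit.params.beta1 == pytest.approx(0.0, abs=1e-12)
        assert fit.params.beta0 == pytest.approx(1.0 / 3.0)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(SingularFitError):
            fit_ols(points_from_arrays([0.5, 0.5, 0.5], [1, 2, 3]))

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_ols(points_from_arrays([0, 1], [0, 1]))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(20160412)
        for _ in range(50):
            n = int(rng.integers(3, 51))
            x = rng.uniform(0.01, 0.5, n)
            if np.ptp(x) == 0:
                continue
            y = 5.6 - 5.7 * x + rng.normal(0, 0.1, n)
            fit = fit_ols(points_from_arrays(x, y))
            b0, b1 = normal_equations(x, y)
            assert fit.params.beta0 == pytest.approx(b0, abs=1e-10)
            assert fit.params.beta1 == pytest.approx(b1, abs=1e-10)

    def test_f_r2_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 40))
            x = rng.uniform(0, 1, n)
            y = 1.0 + 2.0 * x + rng.normal(0, 0.3, n)
            fit = fit_ols(points_from_arrays(x, y))
            expected = fit.r_squared * (n - 2) / (1 - fit.r_squared)
            assert fit.f_stat == pytest.approx(expected, rel=1e-6)

    def test_recovers_truth_within_three_se(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0.01, 0.5, 50)
        y = 5.6 - 5.7 * x + rng.normal(0, 0.1, 50)
        fit = fit_ols(points_from_arrays(x, y))
        assert abs(fit.params.beta0 - 5.6) < 3 * fit.beta0_se
        assert abs(fit.params.beta1 + 5.7) < 3 * fit.beta1_se


class TestDiagnostics:
    def test_leverages_sum_to_parameter_count(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 25)
        y = rng.normal(0, 1, 25)
        diags = diagnostics(points_from_arrays(x, y))
        assert sum(d.leverage for d in diags) == pytest.approx(2.0, abs=1e-9)
        assert all(0.0 <= d.leverage <= 1.0 for d in diags)
        assert all(d.cooks_d >= 0.0 for d in diags)

    def test_zero_residual_point_has_zero_diagnostics(self):
        # residuals orthogonal to the design: OLS recovers the line exactly,
        # and the x=2 point sits on it with residual 0
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        e = np.array([1.0, -2.0, 0.0, 2.0, -1.0])
        y = 2.0 + 0.5 * x + e
        diags = diagnostics(points_from_arrays(x, y))
        zero = diags[2]
        assert zero.residual == pytest.approx(0.0, abs=1e-12)
        assert zero.studentized == pytest.approx(0.0, abs=1e-12)
        assert zero.cooks_d == pytest.approx(0.0, abs=1e-24)

    def test_external_studentized_matches_loo_refit_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.01, 0.5, 20)
        y = 5.6 - 5.7 * x + rng.normal(0, 0.15, 20)
        diags = diagnostics(points_from_arrays(x, y))
        for i, d in enumerate(diags):
            assert d.studentized == pytest.approx(loo_studentized(x, y, i), rel=1e-8)

    def test_cooks_distance_formula(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 15)
        y = 1 + 2 * x + rng.normal(0, 0.2, 15)
        fit = fit_ols(points_from_arrays(x, y))
        diags = diagnostics(points_from_arrays(x, y))
        s2 = fit.residual_variance
        for d in diags:
            expected = d.residual**2 * d.leverage / (2 * s2 * (1 - d.leverage) ** 2)
            assert d.cooks_d == pytest.approx(expected, rel=1e-9)

    def test_shifted_point_has_max_studentized_and_is_flagged(self):
        rng = np.random.default_rng(13)
        x = np.linspace(0.02, 0.4, 30)
        y = 5.6 - 5.7 * x + rng.normal(0, 0.15, 30)
        y[12] += 10 * 0.15
        diags = diagnostics(points_from_arrays(x, y))
        worst = max(diags, key=lambda d: abs(d.studentized))
        assert worst is diags[12]
        assert worst.is_outlier
        assert worst in flag_outliers(diags)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            diagnostics(points_from_arrays([0, 1, 2], [0, 1.1, 1.9]))


class TestFlagRule:
    @pytest.mark.parametrize(
        "studentized,cooks,expected",
        [
            (2.9, 0.5, False),
            (3.1, 0.0, True),
            (0.0, 1.2, True),
            (3.0, 1.0, False),  # strict inequalities: exact threshold not flagged
            (-3.1, 0.0, True),
            (float("nan"), float("nan"), False),
        ],
    )
    def test_threshold_rule(self, studentized, cooks, expected):
        d = DiagnosticsRecord(
            year=2000, x=0.1, y=1.0, residual=0.0, leverage=0.1,
            studentized=studentized, studentized_internal=studentized,
            cooks_d=cooks, is_outlier=expected,
        )
        assert (d in flag_outliers([d])) is expected


class TestFitWithExclusion:
    def _contaminated(self, seed, shift=10.0):
        config = GeneratorConfig(seed=seed, outliers=((1990, shift),))
        series, truth = generate_series(config)
        return transform_series(series), truth

    def test_clean_series_is_noop(self):
        series, _ = generate_series(GeneratorConfig(seed=42, noise_sd=0.05))
        points = transform_series(series)
        result = fit_with_exclusion(points)
        plain = fit_ols(points)
        assert result.excluded == ()
        assert result.params == plain.params
        assert result.n_used == len(points)
        assert len(result.diagnostics) == len(points)

    def test_contaminated_year_excluded_and_fit_improves(self):
        points, truth = self._contaminated(seed=202)
        result = fit_with_exclusion(points)
        assert [year for year, _ in result.excluded] == [1990]
        assert "studentized" in result.excluded[0][1]
        contaminated = fit_ols(points)
        assert abs(result.params.b - (-truth.beta1)) < abs(contaminated.params.b - (-truth.beta1))

    def test_infinite_thresholds_disable_rule(self):
        points, _ = self._contaminated(seed=303)
        result = fit_with_exclusion(points, sr_threshold=math.inf, cooks_threshold=math.inf)
        plain = fit_ols(points)
        assert result.excluded == ()
        assert result.params == plain.params

    def test_few_points_skips_exclusion_with_warning(self):
        points = points_from_arrays([0.0, 0.5, 1.0], [0.0, 0.4, 1.1])
        with pytest.warns(UserWarning):
            result = fit_with_exclusion(points)
        assert result.excluded == ()
        assert result.n_used == 3

    def test_serialisation_round_trip(self):
        series, _ = generate_series(GeneratorConfig(seed=8))
        result = fit_with_exclusion(transform_series(series))
        payload = result.to_dict()
        assert payload["n_used"] == result.n_used
        assert payload["b"] == pytest.approx(result.params.b)
        frame = result.diagnostics_frame()
        assert set(frame.columns) >= {"year", "x", "residual", "leverage", "studentized", "cooks_d", "is_outlier"}
        assert len(frame) == len(result.diagnostics)

    def test_p_value_display_convention(self):
        series, _ = generate_series(GeneratorConfig(seed=77, noise_sd=0.05))
        result = fit_ols(transform_series(series))
        assert result.p_value < 0.001
        assert result.p_value_display == "<0.001"
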