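"""OLS fitting of the log-linear Smeed form with influence diagnostics.

The transformed model Y = beta0 + beta1*X + eps is fitted by ordinary
least squares (via statsmodels).  Per-observation influence diagnostics —
leverage, internally and externally studentized residuals, and Cook's
distance — drive the outlier rule used throughout the package: an
observation is an outlier when its |externally studentized residual|
exceeds 3.0 or its Cook's distance exceeds 1.0 (strict inequalities).
``fit_with_exclusion`` applies the rule in a single diagnose-remove-refit
pass by default; an iterative mode is available but off by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, SingularFitError
from .smeed_core import SmeedParameters, TransformedPoint, params_from_linear

__all__ = [
    "DiagnosticsRecord",
    "FitResult",
    "fit_ols",
    "diagnostics",
    "flag_outliers",
    "fit_with_exclusion",
    "SR_THRESHOLD",
    "COOKS_THRESHOLD",
]

#: Default outlier thresholds: |externally studentized residual| > 3.0
#: or Cook's distance > 1.0.
SR_THRESHOLD = 3.0
COOKS_THRESHOLD = 1.0

#: Parameters in the simple linear model (intercept + slope).
N_PARAMS = 2


@dataclass(frozen=True)
class DiagnosticsRecord:
    """Influence diagnostics for one observation of a fit.

    ``studentized`` is the externally (leave-one-out) studentized residual,
    the variant used for outlier calling; the internally studentized value
    is kept alongside for sensitivity checks.
    """

    year: int
    x: float
    y: float
    residual: float
    leverage: float
    studentized: float
    studentized_internal: float
    cooks_d: float
    is_outlier: bool


@dataclass(frozen=True)
class FitResult:
    """A fitted log-linear Smeed model with goodness-of-fit and diagnostics.

    ``diagnostics`` always refers to the pre-exclusion fit; the scalar
    statistics (r_squared, f_stat, p_value, n_used, standard errors) refer
    to the final fit on ``n_used`` observations.  p-values below 0.001 are
    displayed as "<0.001" but stored at full precision.
    """

    params: SmeedParameters
    r_squared: float
    f_stat: float
    p_value: float
    n_used: int
    residual_variance: float
    beta0_se: float
    beta1_se: float
    diagnostics: tuple[DiagnosticsRecord, ...] = ()
    excluded: tuple[tuple[int, str], ...] = ()

    @property
    def p_value_display(self) -> str:
        return "<0.001" if self.p_value < 0.001 else f"{self.p_value:.3f}"

    def beta1_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1-alpha) t-interval for the slope beta1."""
        t = stats.t.ppf(1 - alpha / 2, df=self.n_used - N_PARAMS)
        return (self.params.beta1 - t * self.beta1_se, self.params.beta1 + t * self.beta1_se)

    def to_dict(self) -> dict:
        return {
            "beta0": self.params.beta0,
            "beta1": self.params.beta1,
            "a": self.params.a,
            "b": self.params.b,
            "r_squared": self.r_squared,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "residual_variance": self.residual_variance,
            "beta0_se": self.beta0_se,
            "beta1_se": self.beta1_se,
            "excluded": [list(e) for e in self.excluded],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def diagnostics_frame(self) -> pd.DataFrame:
        """Diagnostics table (pre-exclusion fit) for CSV export."""
        return pd.DataFrame(
            [
                {
                    "year": d.year,
                    "x": d.x,
                    "y": d.y,
                    "residual": d.residual,
                    "leverage": d.leverage,
                    "studentized": d.studentized,
                    "studentized_internal": d.studentized_internal,
                    "cooks_d": d.cooks_d,
                    "is_outlier": d.is_outlier,
                }
                for d in self.diagnostics
            ]
        )


def _design(points: Sequence[TransformedPoint]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    return x, y


def _check_fit_preconditions(points: Sequence[TransformedPoint]) -> None:
    if len(points) < 3:
        raise InsufficientDataError(
            f"at least 3 points required for a fit, got {len(points)}"
        )
    x = np.array([p.x for p in points], dtype=float)
    if np.ptp(x) == 0.0:
        raise SingularFitError("all motorization values identical; design is singular")


def _ols(points: Sequence[TransformedPoint]):
    x, y = _design(points)
    return sm.OLS(y, sm.add_constant(x)).fit()


def fit_ols(points: Sequence[TransformedPoint]) -> FitResult:
    """Least-squares fit of Y = beta0 + beta1*X on all given points.

    Returns the fitted :class:`SmeedParameters` together with the
    coefficient of determination, the F statistic on (1, n-2) degrees of
    freedom and its p-value, and the coefficient standard errors.
    """
    _check_fit_preconditions(points)
    res = _ols(points)
    beta0, beta1 = res.params
    return FitResult(
        params=params_from_linear(beta0, beta1),
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        n_used=len(points),
        residual_variance=float(res.mse_resid),
        beta0_se=float(res.bse[0]),
        beta1_se=float(res.bse[1]),
    )


def diagnostics(
    points: Sequence[TransformedPoint],
    sr_threshold: float = SR_THRESHOLD,
    cooks_threshold: float = COOKS_THRESHOLD,
) -> list[DiagnosticsRecord]:
    """Influence diagnostics for the OLS fit on these points.

    For observation i with residual e_i and leverage h_i:
    the externally studentized residual is e_i / (s_(i) * sqrt(1 - h_i))
    with s_(i) the leave-one-out residual standard deviation, and Cook's
    distance is e_i^2 * h_i / (2 * s^2 * (1 - h_i)^2) with s^2 the fit's
    residual mean square and 2 the parameter count.
    """
    _check_fit_preconditions(points)
    if len(points) <= 3:
        warnings.warn(
            "diagnostics on 3 or fewer points are numerically unstable "
            "(leave-one-out fits have no residual degrees of freedom)",
            stacklevel=2,
        )
    res = _ols(points)
    influence = res.get_influence()
    leverage = influence.hat_matrix_diag
    resid = res.resid
    with warnings.catch_warnings():
        # leave-one-out variance is 0/0 at n=3; surface as nan, warned above
        warnings.simplefilter("ignore", RuntimeWarning)
        studentized_ext = influence.resid_studentized_external
        studentized_int = influence.resid_studentized_internal
        cooks_d = influence.cooks_distance[0]
    records = []
    for p, e, h, t_ext, t_int, d in zip(
        points, resid, leverage, studentized_ext, studentized_int, cooks_d
    ):
        records.append(
            DiagnosticsRecord(
                year=p.year,
                x=p.x,
                y=p.y,
                residual=float(e),
                leverage=float(h),
                studentized=float(t_ext),
                studentized_internal=float(t_int),
                cooks_d=float(d),
                is_outlier=bool(abs(t_ext) > sr_threshold or d > cooks_threshold),
            )
        )
    return records


def flag_outliers(
    diags: Sequence[DiagnosticsRecord],
    sr_threshold: float = SR_THRESHOLD,
    cooks_threshold: float = COOKS_THRESHOLD,
) -> list[DiagnosticsRecord]:
    """Subset of diagnostics records flagged by the outlier rule.

    A record is flagged when |studentized| > sr_threshold OR
    cooks_d > cooks_threshold; both are strict inequalities, so values
    exactly at a threshold are not flagged.  NaN diagnostics (degenerate
    leave-one-out fits) never flag.
    """
    flagged = []
    for d in diags:
        exceeds_sr = abs(d.studentized) > sr_threshold
        exceeds_cooks = d.cooks_d > cooks_threshold
        if exceeds_sr or exceeds_cooks:
            flagged.append(d)
    return flagged


def _exclusion_reason(
    d: DiagnosticsRecord, sr_threshold: float, cooks_threshold: float
) -> str:
    reasons = []
    if abs(d.studentized) > sr_threshold:
        reasons.append(f"|studentized residual| = {abs(d.studentized):.2f} > {sr_threshold:g}")
    if d.cooks_d > cooks_threshold:
        reasons.append(f"Cook's distance = {d.cooks_d:.2f} > {cooks_threshold:g}")
    return "; ".join(reasons)


def fit_with_exclusion(
    points: Sequence[TransformedPoint],
    sr_threshold: float = SR_THRESHOLD,
    cooks_threshold: float = COOKS_THRESHOLD,
    iterative: bool = False,
) -> FitResult:
    """Fit, flag outliers, remove them and refit.

    The default is a single diagnose-remove-refit pass.  With
    ``iterative=True`` the cycle repeats until no further point is flagged.
    The returned result carries the pre-exclusion diagnostics and the list
    of excluded (year, reason) pairs; its scalar statistics describe the
    final fit.  If an exclusion would leave fewer than 3 points, the fit is
    returned without exclusion and a warning is issued.
    """
    if len(points) < 4:
        warnings.warn(
            "fewer than 4 points: outlier exclusion skipped (a removal could "
            "leave the fit underdetermined)",
            stacklevel=2,
        )
        diags = diagnostics(points, sr_threshold, cooks_threshold)
        base = fit_ols(points)
        return FitResult(**{**base.__dict__, "diagnostics": tuple(diags)})

    initial_diags = tuple(diagnostics(points, sr_threshold, cooks_threshold))
    kept = list(points)
    excluded: list[tuple[int, str]] = []
    diags = initial_diags
    while True:
        flagged = flag_outliers(diags, sr_threshold, cooks_threshold)
        if not flagged:
            break
        if len(kept) - len(flagged) < 3:
            warnings.warn(
                "outlier exclusion would leave fewer than 3 points; "
                "returning the fit without exclusion",
                stacklevel=2,
            )
            kept = list(points)
            excluded = []
            break
        flagged_years = {d.year for d in flagged}
        excluded.extend(
            (d.year, _exclusion_reason(d, sr_threshold, cooks_threshold))
            for d in flagged
        )
        kept = [p for p in kept if p.year not in flagged_years]
        if not iterative:
            break
        diags = diagnostics(kept, sr_threshold, cooks_threshold)

    final = fit_ols(kept)
    return FitResult(
        **{
            **final.__dict__,
            "diagnostics": initial_diags,
            "excluded": tuple(excluded),
        }
    )
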