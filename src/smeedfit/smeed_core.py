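"""Closed-form mathematics of the modified Smeed equation.

The model relates a country's road-traffic mortality to its motorization
level:

    D/P = a * (N/P) * exp(-b * N/P)

with ``D/P`` in deaths per 100,000 persons and ``N/P`` in motor vehicles
per person.  Taking logs gives a simple linear form

    Y = beta0 + beta1 * X,   Y = ln(D/P) - ln(N/P),   X = N/P,

with ``beta0 = ln(a)`` and ``beta1 = -b``, so the curve can be fitted by
ordinary least squares.  For ``b > 0`` the curve is unimodal: mortality
rises with motorization up to the peak at ``X = 1/b``, where it attains its
global maximum ``a/(e*b)`` (the predicted maximum mortality, PMM), and
falls thereafter.  For ``b <= 0`` the curve is monotone and the peak
quantities are undefined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import CountrySeries, adjust_fatality_definition, mortality_per_100k, vehicles_per_person
from .errors import InsufficientDataError, NoInteriorPeakError

__all__ = [
    "SmeedParameters",
    "TransformedPoint",
    "params_from_linear",
    "params_to_linear",
    "transform_series",
    "predict_mortality",
    "mortality_derivative",
    "predicted_maximum_mortality",
    "peak_motorization",
    "curve_frame",
]

logger = logging.getLogger(__name__)

#: Minimum usable observations for a meaningful simple-regression fit.
MIN_POINTS = 3

# Display rounding conventions for reports: full precision is always kept
# internally; these apply only when formatting tables.
ROUND_A = 2
ROUND_B = 2
ROUND_PMM = 1
ROUND_PEAK_X = 3


@dataclass(frozen=True)
class SmeedParameters:
    """Parameters of the modified Smeed curve, stored on the linear scale.

    ``beta0``/``beta1`` are the intercept and slope of the log-linear form;
    the curve-scale parameters are derived views, so ``a = exp(beta0)`` and
    ``b = -beta1`` hold by construction.
    """

    beta0: float
    beta1: float

    @property
    def a(self) -> float:
        """Multiplicative curve parameter, deaths per 100,000 per (vehicle/person)."""
        return math.exp(self.beta0)

    @property
    def b(self) -> float:
        """Exponential-decay parameter, per (vehicle/person)."""
        return -self.beta1

    @classmethod
    def from_curve(cls, a: float, b: float) -> "SmeedParameters":
        """Build parameters from the curve scale (requires a > 0)."""
        if a <= 0:
            raise ValueError(f"curve parameter a must be positive, got {a}")
        return cls(beta0=math.log(a), beta1=-b)


@dataclass(frozen=True)
class TransformedPoint:
    """One (X, Y) regression point; the calendar year is carried for reporting."""

    x: float
    y: float
    year: int


def params_from_linear(beta0: float, beta1: float) -> SmeedParameters:
    """Map fitted intercept/slope to curve parameters (a = e^beta0, b = -beta1)."""
    return SmeedParameters(beta0=float(beta0), beta1=float(beta1))


def params_to_linear(params: SmeedParameters) -> tuple[float, float]:
    """Inverse of :func:`params_from_linear`."""
    return params.beta0, params.beta1


def transform_series(
    series: CountrySeries, min_points: int = MIN_POINTS
) -> list[TransformedPoint]:
    """Map an observed series to log-linear regression points.

    Each usable record yields ``x = N/P`` and ``y = ln(D/P) - ln(x)`` with
    ``D/P`` in deaths per 100,000.  Records with zero deaths or zero
    vehicles fall outside the domain of the logarithm; they are excluded
    and logged rather than raising.  Records still under the 7-day fatality
    definition are converted to 30-day equivalents first, so the transform
    is always on comparable counts.

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_points`` usable points remain.
    """
    points: list[TransformedPoint] = []
    for record in series.records:
        record = adjust_fatality_definition(record)
        if record.deaths <= 0 or record.vehicles <= 0:
            logger.info(
                "excluding %s %d from transform (deaths=%g, vehicles=%g)",
                record.country, record.year, record.deaths, record.vehicles,
            )
            continue
        x = vehicles_per_person(record)
        y = math.log(mortality_per_100k(record)) - math.log(x)
        points.append(TransformedPoint(x=x, y=y, year=record.year))
    if len(points) < min_points:
        raise InsufficientDataError(
            f"series {series.country!r} has {len(points)} usable points; "
            f"at least {min_points} required"
        )
    return points


def predict_mortality(params: SmeedParameters, x):
    """Fitted mortality D/P = a*x*exp(-b*x) at motorization ``x``.

    Accepts a scalar or array; ``x`` must be non-negative (the model is
    defined for motorization levels only).  Returns 0 at x = 0.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("motorization x must be non-negative")
    result = params.a * x_arr * np.exp(-params.b * x_arr)
    return float(result) if np.isscalar(x) or x_arr.ndim == 0 else result


def mortality_derivative(params: SmeedParameters, x):
    """d(D/P)/dx = a*exp(-b*x)*(1 - b*x).

    Positive below the peak (x < 1/b), zero at the peak, negative above.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("motorization x must be non-negative")
    result = params.a * np.exp(-params.b * x_arr) * (1.0 - params.b * x_arr)
    return float(result) if np.isscalar(x) or x_arr.ndim == 0 else result


def predicted_maximum_mortality(params: SmeedParameters) -> float:
    """Global maximum of the fitted curve, PMM = a/(e*b), deaths per 100,000.

    Equals ``predict_mortality(params, 1/b)`` exactly.
    """
    if params.b <= 0:
        raise NoInteriorPeakError(
            f"b = {params.b:g} <= 0: the curve is monotone and has no interior peak"
        )
    return params.a / (math.e * params.b)


def peak_motorization(params: SmeedParameters) -> float:
    """Motorization level at which the curve peaks: 1/b, vehicles per person."""
    if params.b <= 0:
        raise NoInteriorPeakError(
            f"b = {params.b:g} <= 0: the curve is monotone and has no interior peak"
        )
    return 1.0 / params.b


def curve_frame(params: SmeedParameters, x_grid: Sequence[float]) -> pd.DataFrame:
    """Evaluate the fitted curve on an x-grid for export/plotting.

    Returns a DataFrame with columns ``x`` (vehicles per person) and
    ``mortality`` (deaths per 100,000).
    """
    x = np.asarray(list(x_grid), dtype=float)
    return pd.DataFrame({"x": x, "mortality": predict_mortality(params, x)})
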