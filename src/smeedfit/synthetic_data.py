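"""Seeded synthetic country-year panels with the model's statistical structure.

The generator emulates what the analysis assumes about real national data:
motorization N/P grows monotonically over the study years (logistic growth
by default — slow, then fast, then saturating — which is how real
motorization curves look; exponential growth is available for
low-motorization regimes), and the transformed response follows

    Y = beta0 + beta1 * x + eps,    eps ~ Normal(0, noise_sd^2),

i.e. Gaussian noise on the log scale, which is multiplicative (lognormal)
on mortality — the scale on which the model is fitted.  Mortality, deaths
and vehicle counts are then reconstructed so that running the full pipeline
on the generated panel recovers the truth.  Optional point outliers shift
individual years' Y by a stated number of noise standard deviations, and a
7-day fatality definition can be emulated (stored deaths are pre-divided by
1.08 so the I/O adjustment reconstructs the 30-day values).

Defaults reproduce a mid-range study condition: curve parameters from a
representative fitted country (a = 273.42, b = 5.742), 44 annual
observations, motorization growing from 0.01 to 0.35 vehicles per person
through the peak at 1/b = 0.174, and noise_sd = 0.15.

All randomness is owned by the config's mandatory seed; identical configs
produce identical panels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataio import (
    SEVEN_TO_THIRTY_DAY_RATIO,
    CountrySeries,
    CountryYearRecord,
    FatalityDefinition,
    PER_100K,
)
from .errors import ConfigError
from .smeed_core import SmeedParameters

__all__ = [
    "GeneratorConfig",
    "SeriesTruth",
    "TableFixture",
    "generate_series",
    "write_truth",
    "make_table_fixtures",
]

#: Default true parameters: a representative fitted country's curve
#: (a = 273.42, b = 5.742), within the range spanned by national fits.
DEFAULT_PARAMS = SmeedParameters(beta0=5.611, beta1=-5.742)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic country series.

    Parameters
    ----------
    seed:
        Mandatory RNG seed; there is no silent global randomness.
    true_params:
        Curve parameters generating the data.
    years:
        Observation years, ascending; gaps are allowed.
    x_start, x_end:
        Motorization (vehicles per person) at the first and last year.
    trajectory:
        ``"logistic"`` (default) or ``"exponential"`` growth of x over time.
    noise_sd:
        Standard deviation of the Gaussian noise on the Y (log) scale.
    population:
        Persons per year: a constant, or a (start, end) pair ramped linearly.
    outliers:
        Pairs (year, shift) adding ``shift * noise_sd`` to that year's Y.
    definition:
        Fatality definition the stored deaths emulate; under ``SEVEN_DAY``
        the stored counts are divided by 1.08.
    round_deaths:
        Round stored death counts to integers (off by default; the
        analysis keeps counts fractional).
    """

    seed: int
    true_params: SmeedParameters = DEFAULT_PARAMS
    years: tuple[int, ...] = tuple(range(1970, 2014))
    x_start: float = 0.01
    x_end: float = 0.35
    trajectory: str = "logistic"
    noise_sd: float = 0.15
    population: float | tuple[float, float] = 5.0e7
    outliers: tuple[tuple[int, float], ...] = ()
    definition: FatalityDefinition = FatalityDefinition.THIRTY_DAY
    country: str = "Simland"
    source_note: str = "synthetic"
    round_deaths: bool = False
    logistic_steepness: float = 8.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "outliers", tuple((int(y), float(s)) for y, s in self.outliers))
        object.__setattr__(self, "definition", FatalityDefinition.coerce(self.definition))
        if len(self.years) < 2:
            raise ConfigError("at least 2 observation years required")
        if len(set(self.years)) != len(self.years) or list(self.years) != sorted(self.years):
            raise ConfigError("years must be strictly ascending")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.x_start <= 0 or self.x_end <= self.x_start:
            raise ConfigError(
                f"trajectory bounds require 0 < x_start < x_end, "
                f"got ({self.x_start}, {self.x_end})"
            )
        if self.trajectory not in ("logistic", "exponential"):
            raise ConfigError(f"unknown trajectory {self.trajectory!r}")
        unknown = [y for y, _ in self.outliers if y not in self.years]
        if unknown:
            raise ConfigError(f"outlier years not in the series: {unknown}")
        pop = self.population
        if isinstance(pop, tuple):
            if len(pop) != 2 or pop[0] <= 0 or pop[1] <= 0:
                raise ConfigError("population ramp must be a positive (start, end) pair")
        elif pop <= 0:
            raise ConfigError(f"population must be positive, got {pop}")


@dataclass(frozen=True)
class SeriesTruth:
    """Noise-free truth emitted alongside a generated series."""

    beta0: float
    beta1: float
    years: tuple[int, ...]
    x: tuple[float, ...]
    mortality_per_100k: tuple[float, ...]


def _time_fraction(years: Sequence[int]) -> np.ndarray:
    y = np.asarray(years, dtype=float)
    return (y - y[0]) / (y[-1] - y[0])


def _x_trajectory(config: GeneratorConfig) -> np.ndarray:
    u = _time_fraction(config.years)
    if config.trajectory == "exponential":
        return config.x_start * (config.x_end / config.x_start) ** u
    # logistic: normalised sigmoid so endpoints hit x_start / x_end exactly
    k = config.logistic_steepness
    raw = 1.0 / (1.0 + np.exp(-k * (u - 0.5)))
    raw = (raw - raw[0]) / (raw[-1] - raw[0])
    return config.x_start + (config.x_end - config.x_start) * raw


def _population(config: GeneratorConfig) -> np.ndarray:
    u = _time_fraction(config.years)
    pop = config.population
    if isinstance(pop, tuple):
        return pop[0] + (pop[1] - pop[0]) * u
    return np.full(len(config.years), float(pop))


def generate_series(config: GeneratorConfig) -> tuple[CountrySeries, SeriesTruth]:
    """Generate one country series plus its noise-free truth.

    For each year: x follows the configured trajectory,
    Y = beta0 + beta1*x + eps (+ any outlier shift), mortality per 100,000
    is exp(Y)*x, deaths = mortality * population / 100,000, and
    vehicles = x * population.
    """
    rng = np.random.default_rng(config.seed)
    x = _x_trajectory(config)
    population = _population(config)
    beta0, beta1 = config.true_params.beta0, config.true_params.beta1

    y_clean = beta0 + beta1 * x
    y = y_clean + rng.normal(0.0, config.noise_sd, size=len(x))
    shifts = dict(config.outliers)
    for i, year in enumerate(config.years):
        if year in shifts:
            y[i] += shifts[year] * config.noise_sd

    mortality = np.exp(y) * x
    deaths = mortality * population / PER_100K
    vehicles = x * population
    if config.definition is FatalityDefinition.SEVEN_DAY:
        deaths = deaths / SEVEN_TO_THIRTY_DAY_RATIO
    if config.round_deaths:
        deaths = np.round(deaths)

    records = tuple(
        CountryYearRecord(
            country=config.country,
            year=year,
            deaths=float(d),
            vehicles=float(v),
            population=float(p),
            definition=config.definition,
        )
        for year, d, v, p in zip(config.years, deaths, vehicles, population)
    )
    series = CountrySeries(
        country=config.country, records=records, source_note=config.source_note
    )
    truth = SeriesTruth(
        beta0=beta0,
        beta1=beta1,
        years=config.years,
        x=tuple(float(v) for v in x),
        mortality_per_100k=tuple(float(np.exp(beta0 + beta1 * xi) * xi) for xi in x),
    )
    return series, truth


def write_truth(truth: SeriesTruth, path: str | Path) -> None:
    """Write the sidecar truth file (JSON) next to an exported panel."""
    Path(path).write_text(
        json.dumps(
            {
                "beta0": truth.beta0,
                "beta1": truth.beta1,
                "years": list(truth.years),
                "x": list(truth.x),
                "mortality_per_100k": list(truth.mortality_per_100k),
            },
            indent=2,
        )
    )


@dataclass(frozen=True)
class TableFixture:
    """One published per-country fit: coefficients and derived peak values.

    ``beta0``/``beta1`` are the printed regression coefficients; ``a`` is
    the printed curve parameter (which can differ in the last digits from
    exp(beta0) because beta0 is printed to 3 decimals).  ``pmm``,
    ``peak_x`` and ``peak_period`` are the printed derived quantities the
    coefficients should reproduce in closed form.
    """

    country: str
    source: str
    period: str
    beta0: float
    beta1: float
    a: float
    r_squared: float
    f_stat: float
    pmm: float
    peak_x: float
    peak_period: str

    @property
    def params(self) -> SmeedParameters:
        """Parameters on the linear scale (a = exp(beta0))."""
        return SmeedParameters(beta0=self.beta0, beta1=self.beta1)

    @property
    def curve_params(self) -> SmeedParameters:
        """Parameters anchored at the printed a (with b = -beta1)."""
        return SmeedParameters.from_curve(self.a, -self.beta1)

    @property
    def n_years(self) -> int:
        """Number of observation years in the printed time period."""
        total = 0
        for part in self.period.replace("–", "-").split(","):
            if "-" in part:
                lo, hi = part.split("-")
                total += int(hi) - int(lo) + 1
            else:
                total += 1
        return total


# Published per-country fits of the model (14 countries; China appears twice,
# once per data source).  Used as a fixed worked-example fixture set.
_TABLE_ROWS = [
    # country, source, period, beta0, beta1, a, R^2, F, pmm, peak_x, peak period
    ("China", "health data", "2002–2013", 5.611, -5.742, 273.42, 0.852, 51.788, 17.5, 0.174, "2012"),
    ("China", "police data", "1970–2013", 6.243, -16.392, 514.58, 0.831, 209.439, 11.5, 0.061, "2002"),
    ("Belgium", "OECD online library", "1970–2013", 6.241, -5.655, 513.34, 0.982, 2208.767, 33.4, 0.177, "Before 1970"),
    ("Finland", "OECD online library", "1970–2012", 6.228, -7.851, 506.67, 0.900, 197.787, 23.7, 0.127, "Before 1970"),
    ("Greece", "OECD online library", "1970–2013", 5.131, -3.203, 169.17, 0.956, 844.840, 19.4, 0.312, "1993–1994"),
    ("Hungary", "OECD online library", "1970–2013", 5.745, -6.495, 312.75, 0.903, 379.690, 17.7, 0.154, "1977"),
    ("Ireland", "OECD online library", "1970–2013", 5.493, -5.315, 242.89, 0.899, 357.592, 16.8, 0.188, "1970"),
    ("Japan", "OECD online library", "1970–2013", 4.966, -3.787, 143.51, 0.877, 299.996, 13.9, 0.264, "Before 1970"),
    ("Lithuania", "OECD online library", "1989–2013", 5.364, -3.403, 213.58, 0.920, 265.283, 23.1, 0.294, "1996"),
    ("New Zealand", "OECD online library", "1970–2013", 6.052, -4.444, 424.95, 0.836, 203.217, 35.2, 0.225, "Before 1970"),
    ("Poland", "OECD online library", "1970,1975,1980,1985,1990–2013", 5.221, -3.844, 185.12, 0.970, 811.433, 17.7, 0.260, "1990–1991"),
    ("Portugal", "OECD online library", "1970–2012", 6.002, -5.418, 404.42, 0.963, 1056.563, 27.5, 0.185, "1979"),
    ("Slovenia", "OECD online library", "1990–2013", 6.478, -6.185, 650.75, 0.951, 408.871, 38.7, 0.162, "Before 1970"),
    ("Spain", "OECD online library", "1970,1980,1990–2013", 5.288, -3.998, 197.96, 0.859, 140.650, 18.2, 0.250, "1980–1990"),
    ("United States", "OECD online library", "1970–2013", 5.244, -2.709, 189.37, 0.847, 199.475, 25.7, 0.369, "Before 1970"),
]


def make_table_fixtures() -> list[TableFixture]:
    """The 15 published country/source fits as a static fixture set."""
    return [TableFixture(*row) for row in _TABLE_ROWS]
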