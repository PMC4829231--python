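import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smeedfit import CountrySeries, CountryYearRecord, SmeedParameters, make_table_fixtures

settings.register_profile(
    "smeedfit",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("smeedfit")


@pytest.fixture
def china_health_params() -> SmeedParameters:
    """Coefficients of the health-data fit: a=273.42, b=5.742."""
    return SmeedParameters(beta0=5.611, beta1=-5.742)


@pytest.fixture
def table_fixtures():
    return make_table_fixtures()


def make_series(
    x_by_year: dict[int, float],
    mortality_per_100k: float | dict[int, float] = 10.0,
    population: float = 1_000_000.0,
    country: str = "Testland",
) -> CountrySeries:
    """Build a series with prescribed motorization (and mortality) per year."""
    records = []
    for year, x in x_by_year.items():
        m = (
            mortality_per_100k[year]
            if isinstance(mortality_per_100k, dict)
            else mortality_per_100k
        )
        records.append(
            CountryYearRecord(
                country=country,
                year=year,
                deaths=m * population / 100_000.0,
                vehicles=x * population,
                population=population,
            )
        )
    return CountrySeries(country=country, records=tuple(records))


@pytest.fixture
def series_factory():
    return make_series
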