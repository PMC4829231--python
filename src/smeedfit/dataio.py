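"""Reading, validation and normalisation of country-year road-safety panels.

A panel is a plain CSV with one row per (country, year) holding the raw
counts the mortality model consumes: road-traffic deaths ``D``, registered
motor vehicles ``N`` and population ``P``.  Two derived rates are used
throughout the package and fix the unit conventions:

* mortality ``D/P`` is expressed in deaths per 100,000 persons;
* motorization ``N/P`` is expressed in motor vehicles per person.

Death counts recorded under a 7-day post-crash definition are converted to
the international 30-day definition by the standard factor 1.08; the
converted counts are kept at full (fractional) precision because the factor
is a statistical correction, not a recount.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import PanelFormatError

__all__ = [
    "FatalityDefinition",
    "CountryYearRecord",
    "CountrySeries",
    "SEVEN_TO_THIRTY_DAY_RATIO",
    "PER_100K",
    "adjust_fatality_definition",
    "adjust_series",
    "mortality_per_100k",
    "vehicles_per_person",
    "read_panel",
    "write_panel",
]

logger = logging.getLogger(__name__)

#: Conversion factor from 7-day to 30-day road-traffic death counts
#: (European Conference of Ministers of Transport convention).
SEVEN_TO_THIRTY_DAY_RATIO = 1.08

#: Denominator scale for mortality rates.
PER_100K = 100_000.0

PANEL_COLUMNS = ("country", "year", "deaths", "vehicles", "population", "definition")


class FatalityDefinition(str, Enum):
    """Post-crash window within which a death counts as a traffic fatality."""

    SEVEN_DAY = "7day"
    THIRTY_DAY = "30day"

    @classmethod
    def coerce(cls, value: "FatalityDefinition | str") -> "FatalityDefinition":
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower()
        aliases = {
            "7day": cls.SEVEN_DAY,
            "7-day": cls.SEVEN_DAY,
            "seven_day": cls.SEVEN_DAY,
            "30day": cls.THIRTY_DAY,
            "30-day": cls.THIRTY_DAY,
            "thirty_day": cls.THIRTY_DAY,
        }
        try:
            return aliases[text]
        except KeyError:
            raise ValueError(f"unknown fatality definition: {value!r}") from None


@dataclass(frozen=True)
class CountryYearRecord:
    """One observed (year, deaths, vehicles, population) row for a country.

    ``deaths`` and ``vehicles`` are stored as floats: adjusted death counts
    and synthetic data are fractional by design.
    """

    country: str
    year: int
    deaths: float
    vehicles: float
    population: float
    definition: FatalityDefinition = FatalityDefinition.THIRTY_DAY

    def __post_init__(self) -> None:
        object.__setattr__(self, "definition", FatalityDefinition.coerce(self.definition))
        if self.population <= 0:
            raise ValueError(f"population must be positive, got {self.population}")
        if self.deaths < 0:
            raise ValueError(f"deaths must be non-negative, got {self.deaths}")
        if self.vehicles < 0:
            raise ValueError(f"vehicles must be non-negative, got {self.vehicles}")


@dataclass(frozen=True)
class CountrySeries:
    """An ordered (ascending year) run of records for one country.

    Gap years are permitted: the regression treats observations as
    exchangeable points, not a time series.  A series may hold fewer than
    three records at the I/O layer; the minimum of three usable points for
    fitting is enforced where the transformation to regression inputs
    happens.
    """

    country: str
    records: tuple[CountryYearRecord, ...]
    source_note: str = ""

    def __post_init__(self) -> None:
        records = tuple(sorted(self.records, key=lambda r: r.year))
        if not records:
            raise ValueError("CountrySeries requires at least one record")
        years = [r.year for r in records]
        if len(set(years)) != len(years):
            dupes = sorted({y for y in years if years.count(y) > 1})
            raise ValueError(f"duplicate years in series {self.country!r}: {dupes}")
        if any(r.country != self.country for r in records):
            raise ValueError("all records must share the series' country label")
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(r.year for r in self.records)


def adjust_fatality_definition(record: CountryYearRecord) -> CountryYearRecord:
    """Convert a 7-day death count to its 30-day equivalent (factor 1.08).

    Records already under the 30-day definition are returned unchanged, so
    the operation is idempotent.  Adjusted counts are not rounded.
    """
    if record.definition is FatalityDefinition.THIRTY_DAY:
        return record
    return dataclasses.replace(
        record,
        deaths=record.deaths * SEVEN_TO_THIRTY_DAY_RATIO,
        definition=FatalityDefinition.THIRTY_DAY,
    )


def adjust_series(series: CountrySeries) -> CountrySeries:
    """Apply :func:`adjust_fatality_definition` to every record of a series."""
    return dataclasses.replace(
        series, records=tuple(adjust_fatality_definition(r) for r in series.records)
    )


def mortality_per_100k(record: CountryYearRecord) -> float:
    """Road-traffic mortality D/P in deaths per 100,000 persons."""
    if record.population <= 0:
        raise ValueError("population must be positive")
    return record.deaths / record.population * PER_100K


def vehicles_per_person(record: CountryYearRecord) -> float:
    """Motorization level N/P in motor vehicles per person."""
    if record.population <= 0:
        raise ValueError("population must be positive")
    return record.vehicles / record.population


def _resolve_columns(
    columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical panel column names to the columns present in the file."""
    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    for name in PANEL_COLUMNS:
        source = column_map.get(name, name)
        if source in columns:
            resolved[name] = source
        elif name != "definition":
            raise PanelFormatError(
                f"required column {name!r} (looked for {source!r}) not found; "
                f"file has columns {list(columns)}"
            )
    return resolved


def read_panel(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[CountrySeries]:
    """Read a CSV country-year panel into one :class:`CountrySeries` per country.

    Rows with a missing deaths, vehicles or population cell are dropped and
    logged (occasional gaps are expected in national panels).  A missing
    ``definition`` column defaults every row to the 30-day definition.

    Raises
    ------
    PanelFormatError
        If the CSV cannot be parsed (the underlying parser error names the
        offending line) or a (country, year) pair occurs twice.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            # ragged first data row only warns by default; treat as malformed
            warnings.simplefilter("error", pd.errors.ParserWarning)
            frame = pd.read_csv(path, index_col=False)
    except (pd.errors.ParserError, pd.errors.ParserWarning) as exc:
        raise PanelFormatError(f"malformed CSV {path}: {exc}") from exc
    if frame.empty:
        raise PanelFormatError(f"panel {path} contains no data rows")

    cols = _resolve_columns(frame.columns, column_map)

    dup_mask = frame.duplicated(subset=[cols["country"], cols["year"]], keep=False)
    if dup_mask.any():
        dupes = (
            frame.loc[dup_mask, [cols["country"], cols["year"]]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        raise PanelFormatError(
            "duplicate (country, year) rows: "
            + ", ".join(f"({c}, {y})" for c, y in dupes)
        )

    value_cols = [cols["deaths"], cols["vehicles"], cols["population"]]
    missing = frame[value_cols].isna().any(axis=1)
    if missing.any():
        for row in frame.loc[missing].itertuples(index=False):
            logger.warning(
                "dropping row with missing values: %s", dict(row._asdict())
            )
        frame = frame.loc[~missing]

    series_list: list[CountrySeries] = []
    for country, group in frame.groupby(cols["country"], sort=True):
        records = []
        for row in group.itertuples(index=False):
            row = row._asdict()
            definition = (
                row[cols["definition"]]
                if "definition" in cols
                else FatalityDefinition.THIRTY_DAY
            )
            records.append(
                CountryYearRecord(
                    country=str(country),
                    year=int(row[cols["year"]]),
                    deaths=float(row[cols["deaths"]]),
                    vehicles=float(row[cols["vehicles"]]),
                    population=float(row[cols["population"]]),
                    definition=definition,
                )
            )
        series_list.append(CountrySeries(country=str(country), records=tuple(records)))
    return series_list


def write_panel(series: Iterable[CountrySeries], path: str | Path) -> None:
    """Write one or more country series back to the CSV panel format.

    Round-trips with :func:`read_panel` on valid panels.
    """
    rows = [
        {
            "country": r.country,
            "year": r.year,
            "deaths": r.deaths,
            "vehicles": r.vehicles,
            "population": r.population,
            "definition": r.definition.value,
        }
        for s in series
        for r in s.records
    ]
    pd.DataFrame(rows, columns=list(PANEL_COLUMNS)).to_csv(path, index=False)
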