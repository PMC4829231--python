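"""Peak summaries: maximum mortality, peak motorization and peak period.

Given a fitted curve and the observed motorization trajectory, this module
answers the reporting questions: how high does mortality get at its worst
(PMM), at what motorization level does the peak occur (1/b), and during
which calendar period did — or will — the country pass through it.

The peak period is defined as the crossing of the *observed* motorization
trajectory with the fitted peak level 1/b: countries already past the peak
at data start are labelled "Before <first year>", countries not yet there
"After <last year>", and crossings between observed years are labelled by
the bracketing pair of observed years (whatever their gap).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .dataio import CountrySeries, vehicles_per_person
from .regression import FitResult
from .smeed_core import (
    ROUND_PEAK_X,
    ROUND_PMM,
    SmeedParameters,
    peak_motorization,
    predicted_maximum_mortality,
)

__all__ = ["PeakSummary", "locate_peak_year", "summarize", "comparison_table"]

logger = logging.getLogger(__name__)

#: Relative tolerance for calling an observed year an exact peak-year match;
#: matches the 3-decimal display precision of peak motorization.
EXACT_YEAR_RTOL = 1e-3


@dataclass(frozen=True)
class PeakSummary:
    """One report row: a country's fitted peak quantities.

    ``pmm`` and ``peak_x`` are NaN and ``peak_period`` is None when the fit
    has b <= 0 (monotone curve, no interior peak); ``note`` explains.
    """

    country: str
    source_note: str
    pmm: float
    peak_x: float
    peak_period: str | None
    note: str = ""

    @property
    def has_peak(self) -> bool:
        return not math.isnan(self.peak_x)


def locate_peak_year(series: CountrySeries, peak_x: float) -> str:
    """Label the calendar period at which observed motorization crosses peak_x.

    Returns, in order of precedence:

    * ``"Before <first year>"`` if peak_x lies below every observed x;
    * ``"After <last year>"`` if peak_x lies above every observed x;
    * a single year if some observed x matches peak_x to relative
      tolerance 1e-3 (closest such year on ties);
    * otherwise ``"<year_below>–<year_above>"``, the pair of observed years
      bracketing the first crossing (a warning is logged when the
      trajectory is non-monotone and crosses more than once).
    """
    if peak_x <= 0:
        raise ValueError(f"peak_x must be positive, got {peak_x}")
    xs = [vehicles_per_person(r) for r in series.records]
    years = [r.year for r in series.records]

    if peak_x < min(xs):
        return f"Before {years[0]}"
    if peak_x > max(xs):
        return f"After {years[-1]}"

    matches = [
        (abs(x - peak_x) / peak_x, year)
        for x, year in zip(xs, years)
        if abs(x - peak_x) / peak_x <= EXACT_YEAR_RTOL
    ]
    if matches:
        return str(min(matches)[1])

    crossings = [
        i
        for i in range(len(xs) - 1)
        if (xs[i] - peak_x) * (xs[i + 1] - peak_x) < 0
    ]
    if len(crossings) > 1:
        logger.warning(
            "non-monotone motorization trajectory for %s crosses peak_x=%g "
            "%d times; using the first crossing",
            series.country, peak_x, len(crossings),
        )
    i = crossings[0]
    return f"{years[i]}–{years[i + 1]}"


def summarize(series: CountrySeries, fit: FitResult | SmeedParameters) -> PeakSummary:
    """Build the per-country peak summary from a fit.

    Accepts either a full :class:`FitResult` or bare parameters.  For
    b <= 0 the peak fields are marked undefined (NaN / None) rather than
    raising: a monotone regime is a legitimate fit outcome.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    if params.b <= 0:
        return PeakSummary(
            country=series.country,
            source_note=series.source_note,
            pmm=float("nan"),
            peak_x=float("nan"),
            peak_period=None,
            note=f"b = {params.b:g} <= 0: monotone curve, no interior peak",
        )
    peak_x = peak_motorization(params)
    return PeakSummary(
        country=series.country,
        source_note=series.source_note,
        pmm=predicted_maximum_mortality(params),
        peak_x=peak_x,
        peak_period=locate_peak_year(series, peak_x),
    )


def comparison_table(
    summaries: Sequence[PeakSummary],
    reference_countries: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank countries by peak motorization and flag early-peak outliers.

    Rows are sorted by ``peak_x`` ascending (ties broken by country label;
    undefined peaks sort last).  If ``reference_countries`` is given, every
    non-reference entry whose ``peak_x`` falls below the minimum peak_x of
    the reference set is flagged in ``below_reference_min`` — the paper's
    style of argument that a reported peak is implausibly early compared
    with a benchmark group of countries.

    The returned frame's ``attrs`` carry the observed ranges:
    ``pmm_range`` and ``peak_x_range`` as (min, max) tuples.
    """
    if not summaries:
        raise ValueError("comparison_table requires at least one summary")

    ordered = sorted(
        summaries,
        key=lambda s: (math.isnan(s.peak_x), s.peak_x if not math.isnan(s.peak_x) else 0.0, s.country),
    )
    reference = set(reference_countries or ())
    ref_peaks = [s.peak_x for s in ordered if s.country in reference and s.has_peak]
    ref_min = min(ref_peaks) if ref_peaks else float("nan")

    rows = []
    for s in ordered:
        flagged = (
            bool(ref_peaks)
            and s.country not in reference
            and s.has_peak
            and s.peak_x < ref_min
        )
        rows.append(
            {
                "country": s.country,
                "source": s.source_note,
                "pmm": round(s.pmm, ROUND_PMM) if s.has_peak else float("nan"),
                "peak_x": round(s.peak_x, ROUND_PEAK_X) if s.has_peak else float("nan"),
                "peak_period": s.peak_period,
                "below_reference_min": flagged,
                "note": s.note,
            }
        )
    frame = pd.DataFrame(rows)
    with_peak = [s for s in ordered if s.has_peak]
    if with_peak:
        frame.attrs["pmm_range"] = (
            min(s.pmm for s in with_peak),
            max(s.pmm for s in with_peak),
        )
        frame.attrs["peak_x_range"] = (
            min(s.peak_x for s in with_peak),
            max(s.peak_x for s in with_peak),
        )
    frame.attrs["reference_min_peak_x"] = ref_min
    return frame
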