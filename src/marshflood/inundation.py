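"""Hydroperiod metrics: exceedance of plot elevation by a water-level series.

The central operation scans a regularly sampled water-level series for
samples strictly above a plot's elevation and aggregates them into annual
flooding hours, percent of year flooded, and counts/durations of maximal
exceedance events.  Conventions (all deliberate, so results are bit-for-bit
reproducible):

* strict exceedance — a sample is inundated iff ``level > elevation``; exact
  ties count as dry;
* each sample stands for its own interval, so hours = samples × interval/60
  (no interpolation of crossing times);
* missing samples count as *not* inundated and break events; annual data
  coverage is reported alongside, and percent-of-year always uses the full
  calendar-year length (8760 or 8784 h) as the denominator.

Also here: the Mean Higher High Water (MHHW) datum over an epoch, monthly
mean sea level, and seasonal adjustment of a monthly series.
"""

from __future__ import annotations

import calendar
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DatumMismatchError, PlotRecord, WaterLevelSeries

__all__ = [
    "InundationSummary",
    "annual_inundation",
    "inundation_table",
    "summaries_to_frame",
    "compute_mhhw",
    "monthly_mean_sea_level",
    "seasonally_adjust",
    "CoverageError",
]

#: lunar (tidal) day used to partition the record for MHHW, hours
TIDAL_DAY_HOURS = 24.84


class CoverageError(ValueError):
    """Not enough non-missing data to compute the requested statistic."""


@dataclass(frozen=True)
class InundationSummary:
    """Annual hydroperiod summary for one plot.

    ``hours_inundated`` and ``percent_of_year`` are NaN when the year has no
    non-missing samples (``coverage == 0``).  When ``n_events > 0``,
    ``n_events × mean_event_duration == hours_inundated`` exactly.
    """

    plot_id: str
    year: int
    hours_inundated: float
    percent_of_year: float
    n_events: int
    mean_event_duration: float
    coverage: float


def _year_hours(year: int) -> float:
    return (366.0 if calendar.isleap(year) else 365.0) * 24.0


def annual_inundation(
    series: WaterLevelSeries,
    elevation: float,
    plot_id: str = "",
    elevation_datum: str | None = None,
    min_coverage_warn: float = 0.95,
) -> list[InundationSummary]:
    """Annual flooding-hour summaries for a single elevation.

    One summary per calendar year touched by the series span.  Samples the
    series does not cover are treated as missing, which lowers ``coverage``
    but never the denominators.

    Raises
    ------
    DatumMismatchError
        If ``elevation_datum`` is given and differs from the series datum.
    """
    if elevation_datum is not None and elevation_datum != series.datum:
        raise DatumMismatchError(
            f"plot {plot_id!r}: elevation datum {elevation_datum!r} does not match "
            f"water-level datum {series.datum!r}"
        )
    if not np.isfinite(elevation):
        raise ValueError(f"plot {plot_id!r}: elevation must be finite")

    step = pd.Timedelta(minutes=series.interval_minutes)
    hours_per_sample = series.interval_minutes / 60.0
    out: list[InundationSummary] = []
    for year in range(series.start.year, series.end.year + 1):
        y0 = pd.Timestamp(year=year, month=1, day=1)
        y1 = pd.Timestamp(year=year + 1, month=1, day=1)
        n_expected = int(round((y1 - y0) / step))
        # series samples falling inside this calendar year; anything outside
        # the series span is implicitly missing
        lo = max(int(np.ceil((y0 - series.start) / step)), 0)
        hi = min(int(np.ceil((y1 - series.start) / step)), len(series))
        levels = series.levels[lo:hi] if hi > lo else np.empty(0)
        finite = np.isfinite(levels)
        coverage = float(finite.sum()) / n_expected
        if coverage == 0.0:
            out.append(
                InundationSummary(plot_id, year, np.nan, np.nan, 0, np.nan, 0.0)
            )
            continue
        if coverage < min_coverage_warn:
            warnings.warn(
                f"plot {plot_id!r}, {year}: only {coverage:.1%} data coverage",
                stacklevel=2,
            )
        wet = finite & (levels > elevation)
        n_wet = int(wet.sum())
        hours = n_wet * hours_per_sample
        starts = int(wet[0]) + int(np.count_nonzero(wet[1:] & ~wet[:-1]))
        mean_dur = hours / starts if starts else 0.0
        out.append(
            InundationSummary(
                plot_id=plot_id,
                year=year,
                hours_inundated=hours,
                percent_of_year=100.0 * hours / _year_hours(year),
                n_events=starts,
                mean_event_duration=mean_dur,
                coverage=coverage,
            )
        )
    return out


def inundation_table(
    series: WaterLevelSeries,
    plots: Sequence[PlotRecord],
    elevation_datum: str | None = None,
    min_coverage_warn: float = 0.95,
) -> pd.DataFrame:
    """Annual hydroperiod summaries for every plot, as a tidy frame.

    Columns: plot_id, year, hours_inundated, percent_of_year, n_events,
    mean_event_duration, coverage.  One row per (plot, year).
    """
    rows: list[InundationSummary] = []
    for plot in plots:
        rows.extend(
            annual_inundation(
                series,
                plot.elevation,
                plot.plot_id,
                elevation_datum=elevation_datum,
                min_coverage_warn=min_coverage_warn,
            )
        )
    return summaries_to_frame(rows)


def summaries_to_frame(summaries: Sequence[InundationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plot_id": s.plot_id,
                "year": s.year,
                "hours_inundated": s.hours_inundated,
                "percent_of_year": s.percent_of_year,
                "n_events": s.n_events,
                "mean_event_duration": s.mean_event_duration,
                "coverage": s.coverage,
            }
            for s in summaries
        ]
    )


def compute_mhhw(
    series: WaterLevelSeries,
    epoch: tuple[pd.Timestamp | str, pd.Timestamp | str] | None = None,
    min_coverage: float = 0.8,
) -> float:
    """Mean Higher High Water over an epoch (m, series datum).

    The epoch is partitioned into consecutive 24.84-h tidal days starting at
    the epoch start (a trailing partial tidal day is dropped); MHHW is the
    mean over tidal days of the day's highest water level — for a semidiurnal
    regime, the higher of the two high waters.

    Raises
    ------
    CoverageError
        If the epoch holds no complete tidal day or the fraction of
        non-missing samples falls below ``min_coverage``.
    """
    t0 = pd.Timestamp(epoch[0]) if epoch else series.start
    t1 = pd.Timestamp(epoch[1]) if epoch else series.end
    if t1 <= t0:
        raise CoverageError("empty epoch")
    s = series.to_series().loc[t0:t1]
    if s.empty:
        raise CoverageError("epoch outside the series span")
    n_days = int(((t1 - t0) / pd.Timedelta(hours=TIDAL_DAY_HOURS)))
    if n_days < 1:
        raise CoverageError("epoch shorter than one 24.84-h tidal day")
    end_full = t0 + n_days * pd.Timedelta(hours=TIDAL_DAY_HOURS)
    s = s.loc[s.index < end_full]
    cov = float(np.isfinite(s.to_numpy()).mean()) if len(s) else 0.0
    if cov < min_coverage:
        raise CoverageError(
            f"coverage {cov:.1%} below the required {min_coverage:.0%} for MHHW"
        )
    day_index = ((s.index - t0) / pd.Timedelta(hours=TIDAL_DAY_HOURS)).astype(int)
    maxima = s.groupby(day_index).max()
    maxima = maxima.dropna()
    if maxima.empty:
        raise CoverageError("no tidal day with data in the epoch")
    return float(maxima.mean())


def monthly_mean_sea_level(series: WaterLevelSeries) -> pd.Series:
    """Mean of non-missing levels per calendar month (NaN for empty months)."""
    s = series.to_series()
    return s.resample("MS").mean().rename("msl")


def seasonally_adjust(monthly: pd.Series) -> pd.Series:
    """Remove the mean annual cycle from a monthly series.

    Subtracts each calendar month's long-term mean and restores the grand
    mean, so the adjusted series keeps the original level and any trend but
    loses the repeating seasonal signal.  Requires at least 24 non-missing
    months.
    """
    valid = monthly.dropna()
    if len(valid) < 24:
        raise ValueError("seasonal adjustment requires at least 24 non-missing months")
    clim = valid.groupby(valid.index.month).mean()
    adjusted = monthly - monthly.index.month.map(clim)
    return adjusted + float(valid.mean())
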