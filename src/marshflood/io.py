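"""Tabular formats used by the pipeline.

Three file formats are supported, all plain CSV:

* a CO-OPS-style 6-minute water-level export (``Date Time``, ``Water Level``,
  optional ``Quality`` flag column), with datum/station/interval metadata in
  ``#``-prefixed header lines;
* a monitoring-plot table (one row per permanent plot);
* a long-format porewater sample table (one row per replicate measurement).

Readers validate strictly and never drop rows silently: duplicated keys,
misaligned timestamps, unknown zone labels and negative concentrations are
hard errors that name the offending rows.  Missing water levels are kept
*on the sampling grid* (as NaN) so that data-coverage accounting downstream
is exact.  Units are fixed — metres NAVD88 (or whatever datum the header
declares), µM, psu — and are never inferred.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WaterLevelSeries",
    "PlotRecord",
    "PorewaterSample",
    "FormatError",
    "ValidationError",
    "DatumMismatchError",
    "read_coops_water_level",
    "write_coops_water_level",
    "read_plot_table",
    "write_plot_table",
    "read_porewater_table",
    "write_porewater_table",
    "plots_to_frame",
    "samples_to_frame",
]

ZONES = ("high", "mid", "low")
GROWING_SEASON_MONTHS = (5, 6, 7, 8)


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class DatumMismatchError(ValueError):
    """Vertical datums of two inputs disagree; refusing to mix them."""


@dataclass
class WaterLevelSeries:
    """Regularly spaced water levels on a fixed vertical datum.

    ``levels`` is a float array in metres; NaN marks a missing sample that is
    kept on the grid.  ``flags`` optionally carries per-sample quality flags
    (preserved verbatim on round-trip, never interpreted).
    """

    start: pd.Timestamp
    interval_minutes: int
    levels: np.ndarray
    datum: str = "NAVD88"
    station: str = ""
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 1 or self.levels.size < 1:
            raise ValidationError("levels must be a 1-D array with at least one sample")
        if self.interval_minutes <= 0:
            raise ValidationError("interval_minutes must be positive")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=object)
            if self.flags.shape != self.levels.shape:
                raise ValidationError("flags must align with levels")

    def __len__(self) -> int:
        return self.levels.size

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=len(self), freq=pd.Timedelta(minutes=self.interval_minutes)
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.levels, index=self.times(), name="water_level")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(minutes=self.interval_minutes * (len(self) - 1))

    def coverage(self) -> float:
        """Fraction of grid samples that are non-missing."""
        return float(np.isfinite(self.levels).mean())


@dataclass(frozen=True)
class PlotRecord:
    """One permanent 1-m² monitoring plot on a marsh transect."""

    plot_id: str
    segment: str
    transect: int
    position_index: int
    distance_from_forest: float
    elevation: float
    zone: str
    vegetation: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.elevation):
            raise ValidationError(f"plot {self.plot_id}: elevation must be finite")
        if self.zone not in ZONES:
            raise ValidationError(
                f"plot {self.plot_id}: unknown zone {self.zone!r} (allowed: {ZONES})"
            )


@dataclass(frozen=True)
class PorewaterSample:
    """One replicate porewater measurement at a plot in a given month/year.

    Concentrations are µM, salinity psu; NaN marks a missing analyte.
    """

    plot_id: str
    year: int
    month: int
    replicate: int
    nh4: float = np.nan
    po4: float = np.nan
    salinity: float = np.nan

    def __post_init__(self) -> None:
        if self.month not in GROWING_SEASON_MONTHS:
            raise ValidationError(
                f"sample {self.plot_id}/{self.year}-{self.month:02d}: month outside "
                f"growing season {GROWING_SEASON_MONTHS}"
            )
        for name in ("nh4", "po4", "salinity"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValidationError(
                    f"sample {self.plot_id}/{self.year}-{self.month:02d} rep "
                    f"{self.replicate}: negative {name} ({v})"
                )


# ---------------------------------------------------------------------------
# water-level CSV

_WL_HEADER = ["Date Time", "Water Level", "Quality"]
_TS_FMT = "%Y-%m-%d %H:%M"


def write_coops_water_level(series: WaterLevelSeries, path: str | Path) -> None:
    """Write a CO-OPS-style 6-minute CSV with metadata header lines."""
    path = Path(path)
    times = series.times()
    flags = series.flags if series.flags is not None else np.full(len(series), "v", object)
    with path.open("w", newline="") as fh:
        fh.write(f"# station: {series.station}\n")
        fh.write(f"# datum: {series.datum}\n")
        fh.write(f"# interval_minutes: {series.interval_minutes}\n")
        fh.write(",".join(_WL_HEADER) + "\n")
        for t, lvl, flag in zip(times, series.levels, flags):
            val = "" if not np.isfinite(lvl) else f"{lvl:.4f}"
            fh.write(f"{t.strftime(_TS_FMT)},{val},{flag}\n")


def read_coops_water_level(
    path: str | Path,
    datum: str | None = None,
    interval_minutes: int | None = None,
) -> WaterLevelSeries:
    """Read a CO-OPS-style water-level CSV onto a regular grid.

    Rows absent from the file (gaps in the timestamp sequence) become missing
    markers on the grid, so the returned series always has a constant
    interval.  ``datum``/``interval_minutes`` override or supply metadata when
    the file header lacks it.

    Raises
    ------
    FormatError
        On non-monotone or duplicated timestamps, or timestamps not aligned
        to the declared interval (the first offending row is named).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            elif line:
                rows.append(line)
    if not rows:
        raise FormatError(f"{path}: no header row")
    header = [c.strip() for c in rows[0].split(",")]
    try:
        i_time = header.index("Date Time")
        i_level = header.index("Water Level")
    except ValueError as exc:
        raise FormatError(f"{path}: required columns missing from header {header}") from exc
    i_flag = header.index("Quality") if "Quality" in header else None

    interval = interval_minutes or int(meta.get("interval_minutes", 6))
    datum = datum or meta.get("datum")
    if not datum:
        raise FormatError(f"{path}: no datum in header and none supplied")
    station = meta.get("station", "")

    times: list[pd.Timestamp] = []
    levels: list[float] = []
    flags: list[str] = []
    for lineno, row in enumerate(rows[1:], start=2):
        parts = row.split(",")
        try:
            t = pd.Timestamp(parts[i_time])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: unparseable timestamp") from exc
        raw = parts[i_level].strip() if i_level < len(parts) else ""
        lvl = float(raw) if raw else np.nan
        times.append(t)
        levels.append(lvl)
        flags.append(parts[i_flag].strip() if i_flag is not None and i_flag < len(parts) else "")
    if not times:
        raise FormatError(f"{path}: no data rows")

    step = pd.Timedelta(minutes=interval)
    t0 = times[0]
    prev = None
    for lineno, t in enumerate(times, start=2):
        if prev is not None and t <= prev:
            raise FormatError(
                f"{path}:{lineno}: timestamps not strictly increasing at {t}"
            )
        offset = t - t0
        if offset % step != pd.Timedelta(0):
            raise FormatError(
                f"{path}:{lineno}: timestamp {t} not aligned to the "
                f"{interval}-minute grid"
            )
        prev = t
    n = int((times[-1] - t0) // step) + 1
    grid_levels = np.full(n, np.nan)
    grid_flags = np.full(n, "", object)
    for t, lvl, flag in zip(times, levels, flags):
        i = int((t - t0) // step)
        grid_levels[i] = lvl
        grid_flags[i] = flag
    return WaterLevelSeries(t0, interval, grid_levels, datum, station, grid_flags)


# ---------------------------------------------------------------------------
# plot table

_PLOT_COLUMNS = [
    "plot_id",
    "segment",
    "transect",
    "position_index",
    "distance_from_forest_m",
    "elevation_m",
    "zone",
    "vegetation",
]


def plots_to_frame(plots: Sequence[PlotRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(p) for p in plots])
    if df.empty:
        return pd.DataFrame(columns=_PLOT_COLUMNS)
    return df.rename(
        columns={"distance_from_forest": "distance_from_forest_m", "elevation": "elevation_m"}
    )[_PLOT_COLUMNS]


def write_plot_table(plots: Sequence[PlotRecord], path: str | Path) -> None:
    plots_to_frame(plots).to_csv(path, index=False, float_format="%.6g")


def read_plot_table(path: str | Path) -> list[PlotRecord]:
    df = pd.read_csv(path, dtype={"plot_id": str, "segment": str, "zone": str})
    missing = [c for c in _PLOT_COLUMNS if c not in df.columns and c != "vegetation"]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    dupes = df["plot_id"][df["plot_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate plot_id values {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PlotRecord(
                plot_id=row["plot_id"],
                segment=row["segment"],
                transect=int(row["transect"]),
                position_index=int(row["position_index"]),
                distance_from_forest=float(row["distance_from_forest_m"]),
                elevation=float(row["elevation_m"]),
                zone=row["zone"],
                vegetation=str(row.get("vegetation", "") or ""),
            )
        )
    return records


# ---------------------------------------------------------------------------
# porewater table

_PW_COLUMNS = ["plot_id", "year", "month", "replicate", "nh4_um", "po4_um", "salinity_psu"]


def samples_to_frame(samples: Sequence[PorewaterSample]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(s) for s in samples])
    if df.empty:
        return pd.DataFrame(columns=_PW_COLUMNS)
    return df.rename(columns={"nh4": "nh4_um", "po4": "po4_um", "salinity": "salinity_psu"})[
        _PW_COLUMNS
    ]


def write_porewater_table(samples: Sequence[PorewaterSample], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, index=False, float_format="%.6g")


def read_porewater_table(path: str | Path) -> list[PorewaterSample]:
    df = pd.read_csv(path, dtype={"plot_id": str})
    missing = [c for c in _PW_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    key = df[["plot_id", "year", "month", "replicate"]].apply(tuple, axis=1)
    dupes = key[key.duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate sample keys {sorted(set(dupes))[:5]}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            PorewaterSample(
                plot_id=row["plot_id"],
                year=int(row["year"]),
                month=int(row["month"]),
                replicate=int(row["replicate"]),
                nh4=float(row["nh4_um"]) if pd.notna(row["nh4_um"]) else np.nan,
                po4=float(row["po4_um"]) if pd.notna(row["po4_um"]) else np.nan,
                salinity=float(row["salinity_psu"]) if pd.notna(row["salinity_psu"]) else np.nan,
            )
        )
    return samples
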