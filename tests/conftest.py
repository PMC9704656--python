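import numpy as np
import pandas as pd
import pytest

from marshflood import (
    MarshConfig,
    PorewaterConfig,
    TideConfig,
    WaterLevelSeries,
    simulate_marsh,
)


@pytest.fixture(scope="session")
def default_plots():
    return simulate_marsh(MarshConfig(seed=0))


@pytest.fixture
def quiet_tide():
    """One M2-like constituent, no trend/season/noise, one 28-day window."""
    return TideConfig(
        mean_level=0.0,
        constituents=[(1.0, 12.42, 0.0)],
        slr_trend=0.0,
        seasonal_amplitude=0.0,
        noise_sd=0.0,
        start="2015-01-01 00:00",
        end="2015-01-28 23:54",
        seed=0,
    )


@pytest.fixture
def zero_month_effects():
    return {v: {m: 0.0 for m in (5, 6, 7, 8)} for v in ("nh4", "po4", "salinity")}


def make_series(levels, start="2015-01-01", interval=6, datum="NAVD88"):
    return WaterLevelSeries(
        start=pd.Timestamp(start),
        interval_minutes=interval,
        levels=np.asarray(levels, dtype=float),
        datum=datum,
    )


def brute_force_annual(series, elevation):
    """Sample-by-sample hydroperiod counter, independent of the vectorized scan.

    Walks the series one sample at a time, assigning each to its calendar
    year, counting strict exceedances and maximal wet runs (missing samples
    break runs), and dividing by the expected sample count of each year.
    """
    import calendar as _cal

    step = pd.Timedelta(minutes=series.interval_minutes)
    per_year = {}
    for i, level in enumerate(series.levels):
        t = series.start + i * step
        y = t.year
        if y not in per_year:
            n_days = 366 if _cal.isleap(y) else 365
            per_year[y] = {
                "wet": 0, "events": 0, "prev_wet": False, "finite": 0,
                "expected": n_days * 24 * 60 // series.interval_minutes,
            }
        rec = per_year[y]
        if np.isfinite(level):
            rec["finite"] += 1
            wet = level > elevation
        else:
            wet = False
        if wet and not rec["prev_wet"]:
            rec["events"] += 1
        rec["wet"] += int(wet)
        rec["prev_wet"] = wet
    out = {}
    hps = series.interval_minutes / 60.0
    for y, rec in sorted(per_year.items()):
        hours = rec["wet"] * hps
        year_hours = rec["expected"] * hps
        out[y] = {
            "hours": hours,
            "percent": 100.0 * hours / year_hours,
            "events": rec["events"],
            "mean_dur": hours / rec["events"] if rec["events"] else 0.0,
            "coverage": rec["finite"] / rec["expected"],
        }
    return out
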