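"""Synthetic tide, marsh-transect and porewater generators.

These generators produce data with the statistical structure the analysis
pipeline assumes, with known ground truth, so every downstream stage can be
tested without external monitoring data:

* :func:`simulate_water_levels` — a harmonic semidiurnal tide with a linear
  sea-level-rise trend, an annual seasonal cycle and Gaussian noise, sampled
  on a regular (default 6-minute) grid;
* :func:`simulate_marsh` — two marsh segments of parallel transects running
  forest edge → creek bank, with monotonically decreasing (jittered)
  elevations and elevation-threshold zone assignment;
* :func:`simulate_porewater` — triplicate monthly growing-season nutrient and
  salinity samples whose linear time trends are coupled, plot by plot, to the
  plot's rate of change of annual inundation.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    ConfigurationError,
    HOURS_PER_YEAR,
    MarshConfig,
    PorewaterConfig,
    TideConfig,
)
from .io import PlotRecord, PorewaterSample, WaterLevelSeries

__all__ = [
    "simulate_water_levels",
    "simulate_marsh",
    "simulate_porewater",
    "resolve_couplings",
]


def simulate_water_levels(config: TideConfig) -> WaterLevelSeries:
    """Generate a regularly sampled water-level series (m, on ``config.datum``).

    level(t) = mean_level + trend·t + seasonal·sin(2πt/1yr)
               + Σ aᵢ·sin(2πt/Tᵢ + φᵢ) + N(0, noise_sd²),

    with t measured from ``config.start`` and the trend expressed per
    365.25-day year.
    """
    config.validate()
    start = pd.Timestamp(config.start)
    end = pd.Timestamp(config.end)
    times = pd.date_range(start, end, freq=pd.Timedelta(minutes=config.interval))
    t_hours = (times - start) / pd.Timedelta(hours=1)
    t_hours = np.asarray(t_hours, dtype=float)
    t_years = t_hours / HOURS_PER_YEAR

    level = np.full(times.size, float(config.mean_level))
    level += (config.slr_trend / 1000.0) * t_years
    if config.seasonal_amplitude:
        level += config.seasonal_amplitude * np.sin(2.0 * np.pi * t_years)
    for amp, period, phase in config.constituents:
        if amp:
            level += amp * np.sin(2.0 * np.pi * t_hours / period + phase)
    rng = np.random.default_rng(config.seed)
    if config.noise_sd:
        level += rng.normal(0.0, config.noise_sd, size=level.size)
    return WaterLevelSeries(
        start=start,
        interval_minutes=config.interval,
        levels=level,
        datum=config.datum,
        station=config.station,
    )


def simulate_marsh(config: MarshConfig | None = None) -> list[PlotRecord]:
    """Generate permanent monitoring plots along forest→creek transects.

    Elevations decrease linearly from the forest edge to the creek bank with
    small Gaussian jitter at interior plots (endpoints are pinned to the
    configured range so each transect spans it exactly).  Each plot's zone is
    read off its elevation against the segment's zone boundaries; the default
    Segment B layout has a single boundary and therefore no mid zone.
    """
    config = config or MarshConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    plots: list[PlotRecord] = []
    for seg in config.segments:
        for transect in range(1, seg.n_transects + 1):
            n = seg.plots_per_transect
            elev = np.linspace(seg.elevation_forest, seg.elevation_creek, n)
            if config.elevation_jitter_sd and n > 2:
                elev[1:-1] += rng.normal(0.0, config.elevation_jitter_sd, size=n - 2)
            dist = np.linspace(0.0, seg.transect_length_m, n)
            for i in range(n):
                plots.append(
                    PlotRecord(
                        plot_id=f"{seg.name}{transect}-{i + 1}",
                        segment=seg.name,
                        transect=transect,
                        position_index=i + 1,
                        distance_from_forest=float(dist[i]),
                        elevation=float(elev[i]),
                        zone=_zone_of(elev[i], seg.zone_boundaries, seg.zone_labels),
                        vegetation=_vegetation_for_zone(
                            _zone_of(elev[i], seg.zone_boundaries, seg.zone_labels)
                        ),
                    )
                )
    return plots


def _zone_of(elevation: float, boundaries: Sequence[float], labels: Sequence[str]) -> str:
    idx = int(np.searchsorted(np.asarray(boundaries), elevation, side="right"))
    return labels[idx]


def _vegetation_for_zone(zone: str) -> str:
    return {
        "low": "Spartina alterniflora",
        "mid": "mixed meadow (S. patens / D. spicata / Salicornia)",
        "high": "Juncus roemerianus",
    }[zone]


def resolve_couplings(
    plots: Sequence[PlotRecord],
    inundation_rates: Mapping[str, float],
    config: PorewaterConfig,
) -> tuple[float, float]:
    """Return the (NH4, PO4) coupling coefficients the generator will use.

    Explicit ``coupling_*`` values win; a ``None`` coupling is calibrated so
    that the mean low-marsh nutrient trend, coupling × mean(low-marsh
    inundation rate), equals the configured target rate.
    """
    nh4, po4 = config.coupling_nh4, config.coupling_po4
    if nh4 is None or po4 is None:
        low_rates = [inundation_rates[p.plot_id] for p in plots if p.zone == "low"]
        if not low_rates:
            raise ConfigurationError("coupling calibration requires low-marsh plots")
        mean_low = float(np.mean(low_rates))
        if mean_low == 0.0:
            raise ConfigurationError(
                "coupling calibration requires a nonzero mean low-marsh inundation rate"
            )
        if nh4 is None:
            nh4 = config.target_low_nh4_rate / mean_low
        if po4 is None:
            po4 = config.target_low_po4_rate / mean_low
    return float(nh4), float(po4)


def simulate_porewater(
    plots: Sequence[PlotRecord],
    inundation_rates: Mapping[str, float],
    config: PorewaterConfig | None = None,
) -> list[PorewaterSample]:
    """Generate triplicate monthly growing-season porewater samples.

    For each plot × year × month × replicate,

        conc = zone baseline + (coupling · inundation_rate)·(year − first year)
               + month effect + N(0, sd²),  truncated below at the detection floor;

    salinity follows the same form with the (negative) ``salinity_trend`` in
    place of the coupled term.  ``inundation_rates`` maps plot id → rate of
    change of annual hours inundated (h·yr⁻¹·yr⁻¹).
    """
    config = config or PorewaterConfig()
    config.validate()
    missing = [p.plot_id for p in plots if p.plot_id not in inundation_rates]
    if missing:
        raise KeyError(f"no inundation rate supplied for plots {missing}")
    gamma_nh4, gamma_po4 = resolve_couplings(plots, inundation_rates, config)
    rng = np.random.default_rng(config.seed)
    year0 = config.years[0]
    samples: list[PorewaterSample] = []
    for plot in plots:
        rate = inundation_rates[plot.plot_id]
        slopes = {
            "nh4": gamma_nh4 * rate,
            "po4": gamma_po4 * rate,
            "salinity": config.salinity_trend,
        }
        for year in config.years:
            dt = year - year0
            for month in config.months:
                mu = {
                    var: config.baselines[var][plot.zone]
                    + slopes[var] * dt
                    + config.month_effects[var].get(month, 0.0)
                    for var in ("nh4", "po4", "salinity")
                }
                sd = {var: config.noise_sd[var][plot.zone] for var in mu}
                for rep in range(1, config.n_replicates + 1):
                    vals = {
                        var: mu[var] + (rng.normal(0.0, sd[var]) if sd[var] else 0.0)
                        for var in mu
                    }
                    samples.append(
                        PorewaterSample(
                            plot_id=plot.plot_id,
                            year=year,
                            month=month,
                            replicate=rep,
                            nh4=max(vals["nh4"], config.detection_floor),
                            po4=max(vals["po4"], config.detection_floor),
                            salinity=max(vals["salinity"], 0.0),
                        )
                    )
    return samples
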