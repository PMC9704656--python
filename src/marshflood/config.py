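"""Configuration objects for the synthetic generators and the pipeline.

Defaults are calibrated to the North Inlet (SC) monitoring setting the
package emulates: a semidiurnal tide with an 11-year (2009–2019) record at
6-minute spacing, a sea-level-rise trend of 13.2 mm/yr, two marsh segments of
three transects each (9 and 8 plots per transect), and growing-season
(May–August) triplicate porewater sampling whose low-marsh nutrient trends
average 8.96 µM NH4 /yr and 0.86 µM PO4 /yr.

All configs can be loaded from a single YAML file (see :func:`load_pipeline_config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "TideConfig",
    "SegmentLayout",
    "MarshConfig",
    "PorewaterConfig",
    "PipelineConfig",
    "ConfigurationError",
    "load_pipeline_config",
    "HOURS_PER_YEAR",
]

#: one "year" of the linear trend terms, in days (Julian year)
DAYS_PER_YEAR = 365.25
HOURS_PER_YEAR = DAYS_PER_YEAR * 24.0

#: principal lunar semidiurnal (M2) period, hours
M2_PERIOD_H = 12.42


class ConfigurationError(ValueError):
    """A configuration violates its invariants."""


@dataclass
class TideConfig:
    """Harmonic tide + sea-level-rise generator settings.

    ``constituents`` are (amplitude m, period h, phase rad) triples; the
    default is a dominant M2-like semidiurnal term plus small S2 and diurnal
    terms.  ``slr_trend`` is in mm/yr; the seasonal term is a single annual
    sinusoid of amplitude ``seasonal_amplitude`` (m).
    """

    mean_level: float = 0.10
    constituents: Sequence[tuple[float, float, float]] = (
        (0.65, M2_PERIOD_H, 0.0),
        (0.10, 12.00, 1.0),
        (0.08, 23.93, 2.0),
    )
    slr_trend: float = 13.2
    seasonal_amplitude: float = 0.10
    noise_sd: float = 0.05
    start: str | pd.Timestamp = "2009-01-01 00:00"
    end: str | pd.Timestamp = "2019-12-31 23:54"
    interval: int = 6
    datum: str = "NAVD88"
    station: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        if self.interval <= 0 or 60 % self.interval != 0:
            raise ConfigurationError(f"interval {self.interval} must divide 60 minutes")
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ConfigurationError("end must be after start")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for amp, period, _ in self.constituents:
            if amp < 0 or period <= 0:
                raise ConfigurationError("constituent amplitudes >= 0 and periods > 0")
        if self.seasonal_amplitude < 0:
            raise ConfigurationError("seasonal_amplitude must be >= 0")


@dataclass
class SegmentLayout:
    """Geometry of one marsh segment: parallel transects from forest to creek."""

    name: str
    n_transects: int
    plots_per_transect: int
    elevation_forest: float
    elevation_creek: float
    transect_length_m: float
    #: ascending elevation cut-points between zones, paired with ``zone_labels``
    zone_boundaries: tuple[float, ...]
    #: zone label per elevation band, from below the first boundary upward
    zone_labels: tuple[str, ...]

    def validate(self) -> None:
        if self.plots_per_transect not in (8, 9):
            raise ConfigurationError(
                f"segment {self.name}: plots_per_transect must be 8 or 9"
            )
        if len(self.zone_labels) != len(self.zone_boundaries) + 1:
            raise ConfigurationError(
                f"segment {self.name}: need one more zone label than boundary"
            )
        lo = min(self.elevation_creek, self.elevation_forest)
        hi = max(self.elevation_creek, self.elevation_forest)
        for b in self.zone_boundaries:
            if not lo < b < hi:
                raise ConfigurationError(
                    f"segment {self.name}: zone boundary {b} outside elevation "
                    f"range [{lo}, {hi}]"
                )


def _default_segments() -> list[SegmentLayout]:
    return [
        # wide, geologically older platform with a mixed-species mid marsh
        SegmentLayout("A", 3, 9, 1.09, -0.467, 255.0, (0.45, 0.75), ("low", "mid", "high")),
        # abbreviated platform, low marsh covers ~95% of the width, no mid zone
        SegmentLayout("B", 3, 8, 1.117, -0.255, 100.0, (0.95,), ("low", "high")),
    ]


@dataclass
class MarshConfig:
    """Transect layout generator settings (defaults give 51 plots on 6 transects)."""

    segments: list[SegmentLayout] = field(default_factory=_default_segments)
    elevation_jitter_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.elevation_jitter_sd < 0:
            raise ConfigurationError("elevation_jitter_sd must be >= 0")
        for seg in self.segments:
            seg.validate()


@dataclass
class PorewaterConfig:
    """Porewater sample generator settings.

    Concentration at plot p, year t, month m, replicate k is

        zone_baseline + (coupling × inundation_rate_p) × (t − first year)
        + month_effect(m) + Gaussian noise,   truncated below at ``detection_floor``.

    ``coupling_nh4``/``coupling_po4`` are in µM·yr⁻¹ per (h·yr⁻¹·yr⁻¹); when
    left ``None`` they are calibrated at generation time so the *mean*
    low-marsh nutrient trend equals ``target_low_nh4_rate`` /
    ``target_low_po4_rate`` (defaults: the field-observed mean low-marsh
    rates of 8.96 and 0.86 µM/yr).  Salinity declines linearly everywhere at
    ``salinity_trend`` psu/yr.
    """

    baselines: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "nh4": {"high": 15.0, "mid": 28.0, "low": 55.0},
            "po4": {"high": 1.5, "mid": 2.8, "low": 5.3},
            "salinity": {"high": 35.0, "mid": 33.0, "low": 30.0},
        }
    )
    coupling_nh4: float | None = None
    coupling_po4: float | None = None
    target_low_nh4_rate: float = 8.96
    target_low_po4_rate: float = 0.86
    salinity_trend: float = -1.0
    month_effects: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {
            "nh4": {5: -6.0, 6: -2.0, 7: 3.0, 8: 5.0},
            "po4": {5: -0.5, 6: -0.1, 7: 0.2, 8: 0.4},
            "salinity": {5: -1.0, 6: 0.0, 7: 0.5, 8: 0.5},
        }
    )
    noise_sd: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "nh4": {"high": 5.0, "mid": 8.0, "low": 15.0},
            "po4": {"high": 0.4, "mid": 0.6, "low": 1.0},
            "salinity": {"high": 2.0, "mid": 2.0, "low": 2.0},
        }
    )
    detection_floor: float = 0.01
    n_replicates: int = 3
    months: tuple[int, ...] = (5, 6, 7, 8)
    years: tuple[int, ...] = tuple(range(2009, 2020))
    seed: int = 0

    def validate(self) -> None:
        for var, per_zone in self.baselines.items():
            for zone, v in per_zone.items():
                if v <= 0:
                    raise ConfigurationError(f"baseline {var}/{zone} must be > 0")
        if self.detection_floor < 0:
            raise ConfigurationError("detection_floor must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if len(self.years) < 2:
            raise ConfigurationError("need at least two sampling years")


@dataclass
class PipelineConfig:
    """End-to-end run configuration: either synthetic generation or input files."""

    mode: str = "synthetic"  # "synthetic" | "files"
    tide: TideConfig = field(default_factory=TideConfig)
    marsh: MarshConfig = field(default_factory=MarshConfig)
    porewater: PorewaterConfig = field(default_factory=PorewaterConfig)
    water_level_path: str | None = None
    plot_table_path: str | None = None
    porewater_table_path: str | None = None
    elevation_datum: str = "NAVD88"
    alpha: float = 0.05
    zone_model_years: tuple[int, int] = (2009, 2019)
    output_dir: str = "marshflood_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.mode == "files":
            for name in ("water_level_path", "plot_table_path", "porewater_table_path"):
                if getattr(self, name) is None:
                    raise ConfigurationError(f"files mode requires {name}")
        else:
            self.tide.validate()
            self.marsh.validate()
            self.porewater.validate()


def _int_keys(d: Mapping[Any, Any]) -> dict[int, float]:
    return {int(k): float(v) for k, v in d.items()}


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Any omitted key keeps its default; nested sections are ``tide``,
    ``marsh`` (with ``segments`` as a list of mappings) and ``porewater``.
    """
    with Path(path).open() as fh:
        raw: dict[str, Any] = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for key in (
        "mode",
        "water_level_path",
        "plot_table_path",
        "porewater_table_path",
        "elevation_datum",
        "alpha",
        "output_dir",
        "seed",
        "log_level",
    ):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "zone_model_years" in raw:
        cfg.zone_model_years = tuple(int(y) for y in raw["zone_model_years"])

    tide = raw.get("tide", {})
    for key, value in tide.items():
        if key == "constituents":
            cfg.tide.constituents = [tuple(map(float, c)) for c in value]
        elif hasattr(cfg.tide, key):
            setattr(cfg.tide, key, value)
        else:
            raise ConfigurationError(f"unknown tide option {key!r}")

    marsh = raw.get("marsh", {})
    for key, value in marsh.items():
        if key == "segments":
            cfg.marsh.segments = [
                SegmentLayout(
                    name=s["name"],
                    n_transects=int(s["n_transects"]),
                    plots_per_transect=int(s["plots_per_transect"]),
                    elevation_forest=float(s["elevation_forest"]),
                    elevation_creek=float(s["elevation_creek"]),
                    transect_length_m=float(s["transect_length_m"]),
                    zone_boundaries=tuple(float(b) for b in s["zone_boundaries"]),
                    zone_labels=tuple(s["zone_labels"]),
                )
                for s in value
            ]
        elif hasattr(cfg.marsh, key):
            setattr(cfg.marsh, key, value)
        else:
            raise ConfigurationError(f"unknown marsh option {key!r}")

    pw = raw.get("porewater", {})
    for key, value in pw.items():
        if key == "month_effects":
            cfg.porewater.month_effects = {v: _int_keys(m) for v, m in value.items()}
        elif key in ("months", "years"):
            setattr(cfg.porewater, key, tuple(int(v) for v in value))
        elif hasattr(cfg.porewater, key):
            setattr(cfg.porewater, key, value)
        else:
            raise ConfigurationError(f"unknown porewater option {key!r}")

    cfg.validate()
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    """Plain-dict form of a pipeline config (for manifests)."""
    return asdict(cfg)
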