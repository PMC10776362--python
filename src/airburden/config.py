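"""Scenario configuration for the synthetic two-stage clean-air experiment.

A *stage* is the interval between two consecutive calendar years in
``years``.  Defaults describe a China-like staged control programme:
fine-particle levels decline in both stages while peak-season ozone rises
in the first stage and falls in the second.  The default stage magnitudes
are calibrated so that the national population-weighted PM2.5 series
reproduces 68.98 -> 47.13 -> 35.77 ug/m3 and the ozone peak-season series
111.4 -> 121.1 -> 114.9 ug/m3 in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .errors import ConfigurationError

#: National population-weighted PM2.5 levels (ug/m3) used to calibrate the
#: default scenario: 2013 baseline, after stage 1 (2017), after stage 2 (2020).
NATIONAL_PW_PM25 = {2013: 68.98, 2017: 47.13, 2020: 35.77}

#: National population-weighted peak-season O3 levels (ug/m3), same years.
NATIONAL_PW_O3 = {2013: 111.4, 2017: 121.1, 2020: 114.9}


def stage_reduction(level_start: float, level_end: float) -> float:
    """Absolute reduction over a stage (positive when air quality improves)."""
    return level_start - level_end


def percent_decline(level_start: float, level_end: float) -> float:
    """Percent decline over a stage, on the 0-100 scale."""
    if level_start <= 0:
        raise ConfigurationError("percent decline needs a positive start level")
    return 100.0 * (level_start - level_end) / level_start


def _default_age_bands() -> list[tuple[float, Optional[float]]]:
    """GBD-style adult bands: 5-year bands from 25 to 95, then open-ended."""
    bands: list[tuple[float, Optional[float]]] = [
        (lo, lo + 5.0) for lo in range(25, 95, 5)
    ]
    bands.append((95.0, None))
    return bands


def age_band_label(band: tuple[float, Optional[float]]) -> str:
    lo, hi = band
    if hi is None or not math.isfinite(hi):
        return f"{int(lo)}+"
    return f"{int(lo)}-{int(hi) - 1}"


@dataclass(frozen=True)
class StageChange:
    """Mean change of a pollutant field over one stage.

    ``mean`` is a fractional decline for multiplicative stages (PM2.5) or an
    additive ug/m3 delta for additive stages (O3); ``heterogeneity`` scales a
    smooth spatial perturbation field (relative for fractional declines,
    absolute ug/m3 for additive deltas).
    """

    mean: float
    heterogeneity: float = 0.0

    def __post_init__(self):
        if self.heterogeneity < 0:
            raise ConfigurationError("stage heterogeneity must be >= 0")


# Calibrated fractional declines: 21.85/68.98 and 11.36/47.13.
_PM25_STAGE1_FRAC = stage_reduction(68.98, 47.13) / 68.98
_PM25_STAGE2_FRAC = stage_reduction(47.13, 35.77) / 47.13


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic gridded scenario."""

    n_rows: int = 50
    n_cols: int = 50
    years: tuple[int, ...] = (2013, 2017, 2020)

    pm25_baseline_mean: float = 68.98
    pm25_baseline_sd: float = 18.0
    # Stage 1 is spatially uneven (region-targeted controls, ozone growth
    # hotspots); stage 2 is closer to uniform nationwide control.
    pm25_stage_reductions: tuple[StageChange, ...] = (
        StageChange(_PM25_STAGE1_FRAC, 0.35),
        StageChange(_PM25_STAGE2_FRAC, 0.20),
    )

    o3_baseline_mean: float = 111.4
    o3_baseline_sd: float = 12.0
    o3_stage_deltas: tuple[StageChange, ...] = (
        StageChange(+9.7, 8.0),
        StageChange(-6.2, 4.0),
    )
    o3_seasonal_amplitude: float = 0.35

    spatial_corr_length: float = 5.0

    age_bands: tuple[tuple[float, Optional[float]], ...] = field(
        default_factory=lambda: tuple(_default_age_bands())
    )
    aging_rate: float = 0.01
    urban_fraction_range: tuple[float, float] = (0.2, 0.8)
    total_population: float = 1.0e9
    male_share: float = 0.512

    life_expectancy_at_birth: float = 77.6

    seed: int = 0

    # -- derived -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_stages(self) -> int:
        return len(self.years) - 1

    @property
    def band_labels(self) -> list[str]:
        return [age_band_label(b) for b in self.age_bands]

    def stage_pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.years[:-1], self.years[1:]))

    # -- validation --------------------------------------------------------
    def __post_init__(self):
        # accept the plain-dict/list forms produced by to_dict()
        for key in ("pm25_stage_reductions", "o3_stage_deltas"):
            val = tuple(
                s if isinstance(s, StageChange) else StageChange(**s)
                for s in getattr(self, key)
            )
            object.__setattr__(self, key, val)
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "age_bands", tuple(
            (float(lo), None if hi is None else float(hi))
            for lo, hi in self.age_bands))
        object.__setattr__(self, "urban_fraction_range",
                           tuple(self.urban_fraction_range))
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if len(self.years) < 2:
            raise ConfigurationError("need at least two years (one stage)")
        if any(b >= a for a, b in zip(self.years[1:], self.years[:-1])):
            raise ConfigurationError("years must be strictly increasing")
        if len(self.pm25_stage_reductions) != self.n_stages:
            raise ConfigurationError(
                f"expected {self.n_stages} PM2.5 stage reductions, "
                f"got {len(self.pm25_stage_reductions)}"
            )
        if len(self.o3_stage_deltas) != self.n_stages:
            raise ConfigurationError(
                f"expected {self.n_stages} O3 stage deltas, "
                f"got {len(self.o3_stage_deltas)}"
            )
        for name in ("pm25_baseline_mean", "o3_baseline_mean",
                     "total_population", "life_expectancy_at_birth"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("pm25_baseline_sd", "o3_baseline_sd", "aging_rate",
                     "spatial_corr_length"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.urban_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("urban_fraction_range must be within [0, 1]")
        if not self.age_bands:
            raise ConfigurationError("age_bands must be non-empty")
        lowers = [b[0] for b in self.age_bands]
        if lowers != sorted(lowers) or len(set(lowers)) != len(lowers):
            raise ConfigurationError("age bands must have increasing lower bounds")
        if not (0.0 < self.male_share < 1.0):
            raise ConfigurationError("male_share must be in (0, 1)")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        d["pm25_stage_reductions"] = [
            {"mean": s.mean, "heterogeneity": s.heterogeneity}
            for s in self.pm25_stage_reductions
        ]
        d["o3_stage_deltas"] = [
            {"mean": s.mean, "heterogeneity": s.heterogeneity}
            for s in self.o3_stage_deltas
        ]
        d["age_bands"] = [[lo, hi] for lo, hi in self.age_bands]
        d["urban_fraction_range"] = list(self.urban_fraction_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(int(y) for y in d["years"])
        for key in ("pm25_stage_reductions", "o3_stage_deltas"):
            if key in d:
                d[key] = tuple(
                    s if isinstance(s, StageChange) else StageChange(**s)
                    for s in d[key]
                )
        if "age_bands" in d:
            d["age_bands"] = tuple(
                (float(lo), None if hi is None else float(hi))
                for lo, hi in d["age_bands"]
            )
        if "urban_fraction_range" in d:
            d["urban_fraction_range"] = tuple(d["urban_fraction_range"])
        return cls(**d)
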