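"""Gridded exposure/population containers and exposure summary metrics.

Exposure metrics operate on aligned per-cell vectors: population-weighted
means, exceedance fractions against an air-quality standard, per-cell
least-squares trends, direct age standardisation, and the long-term ozone
metric (the peak-season concentration, i.e. the maximum 6-month moving
average of the monthly means of the daily 8-h average).

Peak-season windows do not wrap across calendar years: a year of monthly
means yields exactly 7 candidate windows (Jan-Jun ... Jul-Dec).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError

ArrayLike = Union[np.ndarray, pd.Series, list, tuple]

N_MONTHS = 12
WINDOW = 6  # months in the peak-season moving average


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExposureGrid:
    """Per-cell pollutant concentrations for one calendar year.

    ``pm25_annual`` is indexed by ``cell_id``; ``o3_monthly`` has one row per
    cell and exactly 12 monthly columns (1..12), ug/m3 of the daily 8-h
    average.  The derived peak-season value is computed lazily and cached.
    """

    year: int
    pm25_annual: pd.Series
    o3_monthly: pd.DataFrame
    _o3_peak: Optional[pd.Series] = field(default=None, repr=False)

    def __post_init__(self):
        if (np.asarray(self.pm25_annual) < 0).any():
            raise ValidationError(f"negative PM2.5 concentration in year {self.year}")
        if self.o3_monthly.shape[1] != N_MONTHS:
            raise ValidationError(
                f"o3_monthly must have {N_MONTHS} columns, "
                f"got {self.o3_monthly.shape[1]} in year {self.year}"
            )
        if (self.o3_monthly.to_numpy() < 0).any():
            raise ValidationError(f"negative O3 concentration in year {self.year}")
        if not self.pm25_annual.index.equals(self.o3_monthly.index):
            raise ValidationError(f"PM2.5/O3 cell indexes differ in year {self.year}")

    @property
    def cell_ids(self) -> pd.Index:
        return self.pm25_annual.index

    @property
    def o3_peak_season(self) -> pd.Series:
        if self._o3_peak is None:
            vals = peak_season_matrix(self.o3_monthly.to_numpy())
            self._o3_peak = pd.Series(vals, index=self.o3_monthly.index,
                                      name="o3_peak_season")
        return self._o3_peak


@dataclass
class PopulationGrid:
    """Per-cell population counts for one year, by sex x age band x residence.

    ``counts`` is indexed by ``cell_id`` with a 3-level column MultiIndex
    (sex, age_band, residence) forming the complete subgroup cross-product.
    """

    year: int
    counts: pd.DataFrame

    def __post_init__(self):
        if self.counts.columns.nlevels != 3:
            raise ValidationError("population columns must be (sex, age_band, residence)")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError(f"negative population count in year {self.year}")

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.counts.to_numpy().sum())

    def subgroup_totals(self) -> pd.Series:
        """National counts by (sex, age_band, residence)."""
        return self.counts.sum(axis=0)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def peak_season_concentration(monthly: ArrayLike) -> float:
    """Maximum 6-month moving average of 12 within-year monthly means."""
    arr = np.asarray(monthly, dtype=float)
    if arr.shape != (N_MONTHS,):
        raise ValidationError(f"need exactly {N_MONTHS} monthly values, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValidationError("monthly values must be finite (no missing months)")
    if (arr < 0).any():
        raise ValidationError("monthly concentrations must be non-negative")
    return float(peak_season_matrix(arr[None, :])[0])


def peak_season_matrix(monthly: np.ndarray) -> np.ndarray:
    """Vectorised peak-season values for an (n_cells, 12) matrix."""
    windows = np.lib.stride_tricks.sliding_window_view(monthly, WINDOW, axis=1)
    return windows.mean(axis=2).max(axis=1)


def _aligned(values: ArrayLike, population: ArrayLike) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(values, pd.Series) and isinstance(population, pd.Series):
        if not values.index.equals(population.index):
            population = population.reindex(values.index)
            if population.isna().any():
                raise ValidationError("value/population cell keys do not align")
    v = np.asarray(values, dtype=float)
    p = np.asarray(population, dtype=float)
    if v.shape != p.shape:
        raise ValidationError("values and population must have equal length")
    return v, p


def population_weighted_mean(values: ArrayLike, population: ArrayLike) -> float:
    """Population-weighted mean concentration, sum(C*P)/sum(P)."""
    v, p = _aligned(values, population)
    total = p.sum()
    if total <= 0:
        raise ComputationError("total population must be positive")
    return float((v * p).sum() / total)


def fraction_above(values: ArrayLike, population: ArrayLike, threshold: float) -> float:
    """Population share living in cells strictly above ``threshold``.

    Ties at the threshold count as compliant (strict inequality).
    """
    v, p = _aligned(values, population)
    total = p.sum()
    if total <= 0:
        raise ComputationError("total population must be positive")
    return float(p[v > threshold].sum() / total)


def cell_trend(values: Union[pd.Series, pd.DataFrame]):
    """Ordinary least-squares slope of value on calendar year.

    A Series indexed by year gives a scalar slope; a DataFrame (cells x year
    columns) gives one slope per cell.  Requires at least two distinct years.
    """
    if isinstance(values, pd.Series):
        years = np.asarray(values.index, dtype=float)
        mat = np.asarray(values, dtype=float)[None, :]
        scalar = True
    else:
        years = np.asarray(values.columns, dtype=float)
        mat = values.to_numpy(dtype=float)
        scalar = False
    if len(np.unique(years)) < 2:
        raise ValidationError("trend needs at least two distinct years")
    yc = years - years.mean()
    slope = (mat - mat.mean(axis=1, keepdims=True)) @ yc / (yc @ yc)
    if scalar:
        return float(slope[0])
    return pd.Series(slope, index=values.index, name="trend")


def age_standardized_rate(rates: pd.Series, weights: pd.Series) -> float:
    """Direct standardisation: sum of stratum rates times reference weights."""
    if set(rates.index) != set(weights.index):
        raise ValidationError("rate and weight strata do not match")
    weights = weights.reindex(rates.index)
    if abs(float(weights.sum()) - 1.0) > 1e-9:
        raise ValidationError("reference weights must sum to 1")
    return float((rates * weights).sum())
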