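"""Attributable deaths, years of life lost, and loss of life expectancy.

The chain, per grid cell s, year t, and sex-age-residence subgroup k:

    D_{s,t,k}  = AF(C_{s,t}) * B_{s,k} * P_{s,t,k}
    YLL_{s,t}  = sum_k D_{s,t,k} * LE_k
    LLE_{s,t}  = LE_0 * YLL_{s,t} / P_{s,t}

with AF the attributable fraction from the pollutant/cause exposure-response
curve (age-band-specific where the curve set says so).  PM2.5 uses the
annual-mean concentration, O3 the peak-season value.  The combined burden of
the two pollutants is additive in YLL/LLE; a possible synergistic
interaction between them is a documented caveat, not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .erf import ERFCurve, attributable_fraction, curves_by_pollutant, relative_risk
from .errors import ComputationError, ValidationError
from .exposure import ExposureGrid, PopulationGrid
from .synthetic import MortalitySchedule


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def attributable_deaths(af: float, b: float, p: float) -> float:
    """Deaths attributable to exposure in one stratum: AF * B * P."""
    if not (0.0 <= af < 1.0):
        raise ValidationError(f"attributable fraction must be in [0, 1), got {af}")
    if b < 0 or p < 0:
        raise ValidationError("rate and population must be non-negative")
    return af * b * p


def years_of_life_lost(deaths_by_band: pd.Series, le_by_band: pd.Series) -> float:
    """YLL = sum over age bands of deaths times residual life expectancy."""
    positive = deaths_by_band[deaths_by_band > 0]
    missing = set(positive.index) - set(le_by_band.index)
    if missing:
        raise ValidationError(f"no residual life expectancy for bands with deaths: {sorted(missing)}")
    le = le_by_band.reindex(deaths_by_band.index).fillna(0.0)
    return float((deaths_by_band * le).sum())


def loss_of_life_expectancy(yll: float, population: float, le0: float) -> float:
    """Per-capita loss of life expectancy: LE_0 * YLL / P (years)."""
    if population <= 0:
        raise ComputationError("loss of life expectancy undefined for zero population")
    return le0 * yll / population


# ---------------------------------------------------------------------------
# full computation
# ---------------------------------------------------------------------------

@dataclass
class BurdenResult:
    """Burden tables for one draw (or the central curves).

    ``national``: rows (year, pollutant, cause, sex, age_band, residence)
    with attributable deaths and YLL summed over cells.
    ``cells``: rows (cell_id, year, pollutant) with deaths, YLL, cell
    population, and per-capita LLE.
    """

    national: pd.DataFrame
    cells: pd.DataFrame
    le0: float
    draw: Optional[int]

    def national_total(self, year: int, pollutant: str, column: str = "deaths") -> float:
        t = self.national
        sel = (t["year"] == year) & (t["pollutant"] == pollutant)
        return float(t.loc[sel, column].sum())

    def cell_lle(self, year: int, pollutants: Sequence[str]) -> pd.Series:
        """Combined per-cell LLE for a pollutant set (additive in YLL)."""
        t = self.cells[(self.cells["year"] == year)
                       & (self.cells["pollutant"].isin(list(pollutants)))]
        if t.empty:
            raise ValidationError(f"no burden stored for year {year}, pollutants {pollutants}")
        return t.groupby("cell_id")["lle"].sum()

    def cell_population(self, year: int) -> pd.Series:
        t = self.cells[self.cells["year"] == year]
        return t.groupby("cell_id")["population"].first()


def _af_by_band(curves: list[ERFCurve], conc: np.ndarray, band_labels: list[str],
                draw: Optional[int]) -> np.ndarray:
    """AF matrix (n_cells, n_bands) for one cause's curve list."""
    n_cells, n_bands = conc.size, len(band_labels)
    if len(curves) == 1 and curves[0].age_band == "all":
        af = attributable_fraction(relative_risk(curves[0], conc, draw=draw))
        return np.repeat(af[:, None], n_bands, axis=1)
    by_band = {cv.age_band: cv for cv in curves}
    missing = [b for b in band_labels if b not in by_band]
    if missing:
        raise ComputationError(
            f"cause {curves[0].cause!r} ({curves[0].pollutant}): no curve for "
            f"age bands {missing}")
    out = np.empty((n_cells, n_bands))
    for i, band in enumerate(band_labels):
        out[:, i] = attributable_fraction(relative_risk(by_band[band], conc, draw=draw))
    return out


def compute_burden(
    exposure: dict[int, ExposureGrid],
    population: dict[int, PopulationGrid],
    mortality: MortalitySchedule,
    erf_set: Sequence[ERFCurve],
    years: Optional[Sequence[int]] = None,
    pollutants: Sequence[str] = ("pm25", "o3"),
    causes: Optional[dict[str, Sequence[str]]] = None,
    draw: Optional[int] = None,
) -> BurdenResult:
    """Full burden tables per cell, year, subgroup, cause, and pollutant.

    ``draw=None`` uses the central curves; an integer selects one
    uncertainty draw throughout.  ``causes`` optionally restricts (and
    requires) the cause list per pollutant; by default every cause present
    in the curve set is assessed.
    """
    years = sorted(exposure.keys()) if years is None else list(years)
    grouped = curves_by_pollutant(erf_set)
    if causes is None:
        causes = {pol: sorted(grouped.get(pol, {})) for pol in pollutants}
    for pol in pollutants:
        gaps = [c for c in causes.get(pol, []) if c not in grouped.get(pol, {})]
        if gaps:
            raise ComputationError(f"no exposure-response curve for {pol} causes: {gaps}")

    national_rows = []
    cell_rows = []
    for year in years:
        if year not in exposure or year not in population:
            raise ValidationError(f"inputs missing for requested year {year}")
        expo, pop = exposure[year], population[year]
        if not expo.cell_ids.equals(pop.cell_ids):
            raise ValidationError(f"cell keys differ between exposure and population in {year}")
        counts = pop.counts
        cols = list(counts.columns)  # (sex, age_band, residence)
        band_labels = list(counts.columns.levels[1])
        band_of_col = np.array([band_labels.index(b) for (_, b, _) in cols])
        le_col = mortality.le.reindex(
            [b for (_, b, _) in cols]).to_numpy()
        if np.isnan(le_col).any():
            raise ValidationError("mortality schedule missing residual LE for some age band")
        pop_mat = counts.to_numpy()
        cell_total = pop_mat.sum(axis=1)

        for pol in pollutants:
            conc = (expo.pm25_annual if pol == "pm25" else expo.o3_peak_season).to_numpy()
            d_cell = np.zeros(conc.size)
            yll_cell = np.zeros(conc.size)
            for cause in causes.get(pol, []):
                af_cols = _af_by_band(grouped[pol][cause], conc, band_labels, draw)[
                    :, band_of_col]
                b_col = mortality.rates[cause].reindex(cols).to_numpy()
                if np.isnan(b_col).any():
                    raise ValidationError(f"baseline rate missing for cause {cause!r}")
                d_mat = af_cols * b_col[None, :] * pop_mat
                d_cell += d_mat.sum(axis=1)
                yll_mat = d_mat * le_col[None, :]
                yll_cell += yll_mat.sum(axis=1)
                d_sub = d_mat.sum(axis=0)
                yll_sub = yll_mat.sum(axis=0)
                for j, (sex, band, res) in enumerate(cols):
                    national_rows.append((year, pol, cause, sex, band, res,
                                          d_sub[j], yll_sub[j]))
            for cid, d, y, p in zip(expo.cell_ids, d_cell, yll_cell, cell_total):
                # per-capita LLE is undefined for an unpopulated cell
                lle = mortality.le0 * y / p if p > 0 else np.nan
                cell_rows.append((cid, year, pol, d, y, p, lle))

    national = pd.DataFrame(national_rows, columns=[
        "year", "pollutant", "cause", "sex", "age_band", "residence",
        "deaths", "yll"])
    cells = pd.DataFrame(cell_rows, columns=[
        "cell_id", "year", "pollutant", "deaths", "yll", "population", "lle"])
    return BurdenResult(national=national, cells=cells, le0=mortality.le0, draw=draw)
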