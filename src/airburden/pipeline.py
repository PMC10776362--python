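"""End-to-end orchestration: bundle I/O, Monte Carlo uncertainty, run driver.

Uncertainty is propagated by recomputing the burden chain once per
exposure-response draw and reporting empirical percentile intervals
(linear interpolation between order statistics — pinned so confidence
intervals are bit-reproducible).  Uncertainty is not computed for the
Lorenz curves and Gini indexes; that remains an experimental flag.

All result tables are delimited text written with a fixed float format, so
a re-run under the same seed and configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import BurdenResult, compute_burden
from .config import ScenarioConfig
from .equity import gain_of_life_expectancy, gini_index, lorenz_curve
from .erf import ERFCurve, load_erf_table, save_erf_table
from .errors import ComputationError, ConfigurationError, SchemaError, ValidationError
from .exposure import (ExposureGrid, PopulationGrid, fraction_above,
                       population_weighted_mean, cell_trend)
from .synthetic import (RESIDENCES, SEXES, MortalitySchedule, SyntheticBundle,
                        make_scenario)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"
PM25_STANDARD = 35.0   # national ambient annual standard / WHO interim target 1
O3_STANDARD = 100.0    # WHO interim target for peak-season O3


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    scenario: Optional[ScenarioConfig] = None
    input_dir: Optional[str] = None
    out_dir: str = "results/run"
    stage_pairs: Optional[list[tuple[int, int]]] = None
    pollutants: tuple[str, ...] = ("pm25", "o3")
    n_draws: int = 100
    ci_level: float = 0.95
    seed: int = 0
    erf_noise_scale: float = 0.1
    drop_negative_gle: bool = False
    tmrel_sampling: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigurationError("ci_level must be in (0, 1)")
        if self.n_draws < 1:
            raise ConfigurationError("n_draws must be >= 1")
        if self.scenario is None and self.input_dir is None:
            self.scenario = ScenarioConfig(seed=self.seed)

    def resolved_stage_pairs(self, years: Sequence[int]) -> list[tuple[int, int]]:
        pairs = self.stage_pairs or list(zip(years[:-1], years[1:]))
        for y1, y2 in pairs:
            if y1 not in years or y2 not in years:
                raise ConfigurationError(f"stage pair ({y1}, {y2}) references unavailable years")
        return [(int(a), int(b)) for a, b in pairs]

    def to_dict(self) -> dict:
        d = {
            "input_dir": self.input_dir, "out_dir": self.out_dir,
            "stage_pairs": [list(p) for p in self.stage_pairs] if self.stage_pairs else None,
            "pollutants": list(self.pollutants), "n_draws": self.n_draws,
            "ci_level": self.ci_level, "seed": self.seed,
            "erf_noise_scale": self.erf_noise_scale,
            "drop_negative_gle": self.drop_negative_gle,
            "tmrel_sampling": self.tmrel_sampling, "log_level": self.log_level,
        }
        d["scenario"] = self.scenario.to_dict() if self.scenario else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("scenario"):
            d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        if d.get("stage_pairs"):
            d["stage_pairs"] = [tuple(p) for p in d["stage_pairs"]]
        if d.get("pollutants"):
            d["pollutants"] = tuple(d["pollutants"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise SchemaError(f"{path}: run config must be a mapping")
        try:
            return cls.from_dict(d)
        except TypeError as exc:
            raise SchemaError(f"{path}: {exc}") from exc

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# bundle serialisation (long-format delimited tables + config echo)
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, out_dir: Union[str, Path]) -> None:
    """Serialise a bundle: one long table per component plus a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for year, grid in sorted(bundle.exposure.items()):
        rows.append(pd.DataFrame({
            "cell_id": grid.cell_ids, "year": year, "pollutant": "pm25",
            "month": "annual", "value": grid.pm25_annual.to_numpy()}))
        monthly = grid.o3_monthly.stack().rename("value").reset_index()
        monthly["year"] = year
        monthly["pollutant"] = "o3"
        monthly["month"] = monthly["month"].astype(str)
        rows.append(monthly[["cell_id", "year", "pollutant", "month", "value"]])
    pd.concat(rows, ignore_index=True).to_csv(
        out / "exposure.csv", index=False, float_format=FLOAT_FMT)

    pops = []
    for year, grid in sorted(bundle.population.items()):
        t = grid.counts.stack(["sex", "age_band", "residence"], future_stack=True)
        t = t.rename("count").reset_index()
        t["year"] = year
        pops.append(t[["cell_id", "year", "sex", "age_band", "residence", "count"]])
    pd.concat(pops, ignore_index=True).to_csv(
        out / "population.csv", index=False, float_format=FLOAT_FMT)

    mort = bundle.mortality.rates.stack().rename("rate").reset_index()
    mort.columns = ["sex", "age_band", "residence", "cause", "rate"]
    mort["le_k"] = mort["age_band"].map(bundle.mortality.le)
    mort.to_csv(out / "mortality.csv", index=False, float_format=FLOAT_FMT)

    save_erf_table(bundle.erf_set, out / "erf.csv")

    echo = {"scenario": bundle.config.to_dict(),
            "le0": bundle.mortality.le0}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)


def read_inputs(in_dir: Union[str, Path]) -> SyntheticBundle:
    """Read and validate a serialised bundle (schema + key alignment)."""
    src = Path(in_dir)
    for name in ("exposure.csv", "population.csv", "mortality.csv", "erf.csv",
                 "config.yaml"):
        if not (src / name).exists():
            raise SchemaError(f"missing input file: {src / name}")
    with open(src / "config.yaml") as fh:
        echo = yaml.safe_load(fh)
    config = ScenarioConfig.from_dict(echo["scenario"])

    expo_t = pd.read_csv(src / "exposure.csv")
    exposure: dict[int, ExposureGrid] = {}
    for year, grp in expo_t.groupby("year"):
        pm = grp[(grp["pollutant"] == "pm25") & (grp["month"] == "annual")]
        o3 = grp[grp["pollutant"] == "o3"].copy()
        if pm.empty or o3.empty:
            raise SchemaError(f"exposure table incomplete for year {year}")
        o3["month"] = o3["month"].astype(int)
        o3_wide = o3.pivot(index="cell_id", columns="month", values="value")
        if o3_wide.isna().any().any() or o3_wide.shape[1] != 12:
            bad = o3_wide.index[o3_wide.isna().any(axis=1)].tolist()[:5]
            raise SchemaError(f"year {year}: O3 monthly series incomplete (cells {bad} ...)")
        pm_series = pm.set_index("cell_id")["value"].sort_index().rename("pm25_annual")
        try:
            exposure[int(year)] = ExposureGrid(
                year=int(year), pm25_annual=pm_series, o3_monthly=o3_wide.sort_index())
        except ValidationError as exc:
            raise SchemaError(str(exc)) from exc

    pop_t = pd.read_csv(src / "population.csv")
    population: dict[int, PopulationGrid] = {}
    expected = pd.MultiIndex.from_product(
        [SEXES, config.band_labels, RESIDENCES],
        names=["sex", "age_band", "residence"])
    for year, grp in pop_t.groupby("year"):
        wide = grp.pivot(index="cell_id", columns=["sex", "age_band", "residence"],
                         values="count")
        missing = expected.difference(wide.columns)
        if len(missing):
            sex, band, res = missing[0]
            raise SchemaError(
                f"population table year {year}: missing subgroup stratum "
                f"(sex={sex}, age_band={band}, residence={res})")
        wide = wide.reindex(columns=expected)
        if wide.isna().any().any():
            cell = wide.index[wide.isna().any(axis=1)][0]
            raise SchemaError(f"population table year {year}: incomplete strata at cell {cell}")
        try:
            population[int(year)] = PopulationGrid(year=int(year), counts=wide.sort_index())
        except ValidationError as exc:
            raise SchemaError(str(exc)) from exc

    mort_t = pd.read_csv(src / "mortality.csv")
    rates = mort_t.pivot(index=["sex", "age_band", "residence"], columns="cause",
                         values="rate")
    if rates.isna().any().any():
        raise SchemaError("mortality table: ragged cause columns")
    le = (mort_t.drop_duplicates(["age_band"]).set_index("age_band")["le_k"]
          .reindex(config.band_labels))
    if le.isna().any():
        raise SchemaError("mortality table: missing residual LE for some age band")
    rates = rates.reindex(pd.MultiIndex.from_product(
        [SEXES, config.band_labels, RESIDENCES],
        names=["sex", "age_band", "residence"]))
    if rates.isna().any().any():
        raise SchemaError("mortality table: missing subgroup strata")
    try:
        mortality = MortalitySchedule(rates=rates, le=le, le0=float(echo["le0"]))
    except ValidationError as exc:
        raise SchemaError(str(exc)) from exc

    erf_set = load_erf_table(src / "erf.csv")

    truth = {}
    if (src / "truth.json").exists():
        with open(src / "truth.json") as fh:
            truth = json.load(fh)

    bundle = SyntheticBundle(config=config, exposure=exposure, population=population,
                             mortality=mortality, erf_set=erf_set, truth=truth)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class IntervalEstimate:
    """Central estimate with an empirical percentile interval."""

    central: float
    lower: float
    upper: float
    n_draws: int
    draws: Optional[np.ndarray] = field(default=None, repr=False)

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def monte_carlo(
    metric: Callable[[Optional[int]], float],
    n_draws: int,
    ci_level: float = 0.95,
) -> IntervalEstimate:
    """Empirical interval of ``metric`` across exposure-response draws.

    ``metric(None)`` must give the central estimate; ``metric(d)`` the value
    under draw ``d``.  Percentiles use linear interpolation between order
    statistics.  The central estimate is not guaranteed to lie inside the
    interval (it uses the central curve, not the draw median); a warning is
    emitted when it does not.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    central = metric(None)
    vals = np.empty(n_draws)
    for d in range(n_draws):
        try:
            vals[d] = metric(d)
        except Exception as exc:
            raise ComputationError(f"metric failed on draw {d}: {exc}") from exc
    alpha = 1.0 - ci_level
    lower, upper = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)],
                                 method="linear")
    if not (lower <= central <= upper):
        warnings.warn(
            f"central estimate {central:.6g} lies outside the "
            f"{100 * ci_level:.0f}% draw interval ({lower:.6g}, {upper:.6g})",
            stacklevel=2)
    return IntervalEstimate(central=float(central), lower=float(lower),
                            upper=float(upper), n_draws=n_draws, draws=vals)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _exposure_summary(bundle: SyntheticBundle, pollutants: Sequence[str]) -> pd.DataFrame:
    rows = []
    years = sorted(bundle.exposure)
    for year in years:
        grid, pop = bundle.exposure[year], bundle.population[year]
        weights = pop.cell_totals
        if "pm25" in pollutants:
            pm = grid.pm25_annual
            rows.append((year, "pm25_pw_mean", population_weighted_mean(pm, weights)))
            rows.append((year, "pm25_fraction_above_35",
                         fraction_above(pm, weights, PM25_STANDARD)))
        if "o3" in pollutants:
            o3 = grid.o3_peak_season
            rows.append((year, "o3_peak_pw_mean", population_weighted_mean(o3, weights)))
            rows.append((year, "o3_fraction_above_100",
                         fraction_above(o3, weights, O3_STANDARD)))
    if len(years) >= 2 and "pm25" in pollutants:
        wide = pd.DataFrame({y: bundle.exposure[y].pm25_annual for y in years})
        slopes = cell_trend(wide)
        rows.append((years[-1], "pm25_trend_mean_slope", float(slopes.mean())))
    return pd.DataFrame(rows, columns=["year", "metric", "value"])


def _stage_equity(
    burden_central: BurdenResult,
    bundle: SyntheticBundle,
    pairs: Sequence[tuple[int, int]],
    pollutants: Sequence[str],
    drop_negative: bool,
):
    """GLE fields, Lorenz points, and Gini per stage; returns tables + skips."""
    gle_tables, lorenz_tables, gini_rows, skipped = {}, {}, [], []
    for y1, y2 in pairs:
        lle1 = burden_central.cell_lle(y1, pollutants)
        lle2 = burden_central.cell_lle(y2, pollutants)
        p1 = burden_central.cell_population(y1)
        p2 = burden_central.cell_population(y2)
        fld = gain_of_life_expectancy(lle1, lle2, p1, p2, burden_central.le0,
                                      y1=y1, y2=y2)
        gle_tables[(y1, y2)] = fld
        try:
            lz = lorenz_curve(fld.gle.to_numpy(), fld.p_y2.to_numpy(),
                              cell_ids=fld.table.index.to_numpy(),
                              drop_negative=drop_negative)
            gi = gini_index(lz)
        except ComputationError as exc:
            log.warning("stage %s-%s: %s; Lorenz/Gini skipped", y1, y2, exc)
            skipped.append({"stage": [y1, y2], "reason": str(exc)})
            continue
        lorenz_tables[(y1, y2)] = lz
        mean_gle_months = 12.0 * population_weighted_mean(fld.gle, fld.p_y2)
        gini_rows.append((y1, y2, "+".join(pollutants), mean_gle_months, gi,
                          lz.n_negative_cells))
    gini_df = pd.DataFrame(gini_rows, columns=[
        "y1", "y2", "pollutants", "mean_gle_months", "gini", "n_negative_cells"])
    return gle_tables, lorenz_tables, gini_df, skipped


def _draw_metrics(
    bundle: SyntheticBundle,
    pairs: Sequence[tuple[int, int]],
    pollutants: Sequence[str],
    draw: Optional[int],
) -> dict[str, float]:
    """All interval-tracked scalar metrics for one draw in a single pass."""
    res = compute_burden(bundle.exposure, bundle.population, bundle.mortality,
                         bundle.erf_set, pollutants=pollutants, draw=draw)
    out: dict[str, float] = {}
    for year in sorted(bundle.exposure):
        for pol in pollutants:
            out[f"deaths:{pol}:{year}"] = res.national_total(year, pol, "deaths")
            out[f"yll:{pol}:{year}"] = res.national_total(year, pol, "yll")
    for y1, y2 in pairs:
        lle1 = res.cell_lle(y1, pollutants)
        lle2 = res.cell_lle(y2, pollutants)
        p2 = res.cell_population(y2)
        fld = gain_of_life_expectancy(lle1, lle2, res.cell_population(y1), p2,
                                      res.le0, y1=y1, y2=y2)
        out[f"gle_months:{'+'.join(pollutants)}:{y1}-{y2}"] = \
            12.0 * population_weighted_mean(fld.gle, fld.p_y2)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write result tables, a log, and a manifest.

    Returns the manifest dictionary.  Outputs under ``config.out_dir``:
    exposure_summary.csv, burden_national.csv, burden_cells.csv,
    gle_<y1>_<y2>.csv, lorenz_<y1>_<y2>.csv, gini_summary.csv,
    intervals.csv, config_echo.yaml, manifest.json, pipeline.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("airburden")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    outputs, skipped = [], []
    try:
        if config.input_dir is not None:
            bundle = read_inputs(config.input_dir)
        else:
            bundle = make_scenario(config.scenario, n_draws=config.n_draws,
                                   erf_noise_scale=config.erf_noise_scale,
                                   tmrel_sampling=config.tmrel_sampling)
        years = sorted(bundle.exposure)
        pairs = config.resolved_stage_pairs(years)

        def save(df: pd.DataFrame, name: str) -> None:
            df.to_csv(out / name, index=False, float_format=FLOAT_FMT)
            outputs.append(name)

        save(_exposure_summary(bundle, config.pollutants), "exposure_summary.csv")

        central = compute_burden(bundle.exposure, bundle.population,
                                 bundle.mortality, bundle.erf_set,
                                 pollutants=config.pollutants, draw=None)
        save(central.national, "burden_national.csv")
        save(central.cells, "burden_cells.csv")

        gle_tables, lorenz_tables, gini_df, eq_skipped = _stage_equity(
            central, bundle, pairs, config.pollutants, config.drop_negative_gle)
        skipped.extend(eq_skipped)
        for (y1, y2), fld in gle_tables.items():
            save(fld.table.reset_index(), f"gle_{y1}_{y2}.csv")
        for (y1, y2), lz in lorenz_tables.items():
            save(lz.points, f"lorenz_{y1}_{y2}.csv")
        save(gini_df, "gini_summary.csv")

        if config.n_draws >= 2:
            per_draw = [_draw_metrics(bundle, pairs, config.pollutants, d)
                        for d in range(config.n_draws)]
            central_metrics = _draw_metrics(bundle, pairs, config.pollutants, None)
            alpha = 1.0 - config.ci_level
            int_rows = []
            for key in central_metrics:
                vals = np.array([m[key] for m in per_draw])
                lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)],
                                       method="linear")
                int_rows.append((key, central_metrics[key], lo, hi, config.n_draws))
            save(pd.DataFrame(int_rows, columns=[
                "metric", "central", "lower", "upper", "n_draws"]), "intervals.csv")
        else:
            skipped.append({"stage": "intervals", "reason": "n_draws < 2"})

        with open(out / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        outputs.append("config_echo.yaml")

        manifest = {
            "config_hash": config.config_hash(),
            "package_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "cell_id_convention": "row-major from the north-west corner",
            "le0": bundle.mortality.le0,
            "outputs": outputs,
            "skipped": skipped,
            "status": "ok",
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        log.info("pipeline complete: %d outputs in %s", len(outputs), out)
        return manifest
    except Exception:
        manifest = {"status": "failed", "outputs": outputs, "skipped": skipped}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
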