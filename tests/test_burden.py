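"""Burden chain: elementary identities, composition, and a loop oracle."""

import numpy as np
import pandas as pd
import pytest

from airburden import (ComputationError, ValidationError,
                       attributable_deaths, attributable_fraction,
                       compute_burden, loss_of_life_expectancy, relative_risk,
                       years_of_life_lost)
from airburden.erf import curves_by_pollutant


class TestElementaryOperations:
    def test_attributable_deaths_examples(self):
        assert attributable_deaths(0.2, 0.01, 1000.0) == pytest.approx(2.0)
        assert attributable_deaths(0.0, 0.01, 1000.0) == 0.0
        # additivity over disjoint strata with a common AF
        split = attributable_deaths(0.3, 0.02, 400.0) + attributable_deaths(0.3, 0.02, 600.0)
        assert split == pytest.approx(attributable_deaths(0.3, 0.02, 1000.0))

    def test_attributable_deaths_validates_inputs(self):
        with pytest.raises(ValidationError):
            attributable_deaths(1.2, 0.01, 10.0)
        with pytest.raises(ValidationError):
            attributable_deaths(0.1, -0.01, 10.0)

    def test_yll_examples_and_permutation_symmetry(self):
        d = pd.Series({"25-29": 0.0, "65-69": 2.0})
        le = pd.Series({"25-29": 55.0, "65-69": 20.0})
        assert years_of_life_lost(d, le) == pytest.approx(40.0)
        assert years_of_life_lost(d * 0.0, le) == 0.0
        perm = years_of_life_lost(d.iloc[::-1], le)
        assert perm == pytest.approx(years_of_life_lost(d, le))

    def test_yll_missing_le_with_deaths_errors(self):
        d = pd.Series({"65-69": 2.0})
        with pytest.raises(ValidationError):
            years_of_life_lost(d, pd.Series({"25-29": 55.0}))

    def test_lle_examples(self):
        assert loss_of_life_expectancy(40.0, 1000.0, 80.0) == pytest.approx(3.2)
        assert loss_of_life_expectancy(0.0, 1000.0, 80.0) == 0.0
        assert loss_of_life_expectancy(80.0, 2000.0, 80.0) == pytest.approx(
            loss_of_life_expectancy(40.0, 1000.0, 80.0))
        with pytest.raises(ComputationError):
            loss_of_life_expectancy(40.0, 0.0, 80.0)


class TestComputeBurden:
    def test_exposure_below_tmrel_gives_zero_burden(self, small_bundle):
        exposure = {
            y: type(g)(year=g.year,
                       pm25_annual=g.pm25_annual * 0.0 + 1.0,
                       o3_monthly=g.o3_monthly * 0.0 + 1.0)
            for y, g in small_bundle.exposure.items()}
        res = compute_burden(exposure, small_bundle.population,
                             small_bundle.mortality, small_bundle.erf_set)
        assert res.national["deaths"].sum() == 0.0
        assert res.cells["yll"].sum() == 0.0

    def test_single_stratum_matches_hand_chain(self, small_bundle):
        """One cell, one cause: pipeline equals AF*B*P -> *LE -> *LE0/P."""
        bundle = small_bundle
        year = bundle.config.years[0]
        res = compute_burden(bundle.exposure, bundle.population, bundle.mortality,
                             bundle.erf_set, years=[year],
                             pollutants=("o3",), causes={"o3": ["copd"]})
        cell = 3
        conc = float(bundle.exposure[year].o3_peak_season.iloc[cell])
        curve = next(cv for cv in bundle.erf_set if cv.pollutant == "o3")
        af = attributable_fraction(relative_risk(curve, conc))
        counts = bundle.population[year].counts.iloc[cell]
        expected_d, expected_yll = 0.0, 0.0
        for (sex, band, rez), p in counts.items():
            b = bundle.mortality.rates.loc[(sex, band, rez), "copd"]
            d = attributable_deaths(af, b, p)
            expected_d += d
            expected_yll += d * bundle.mortality.le[band]
        row = res.cells[(res.cells["cell_id"] == cell)]
        assert float(row["deaths"].iloc[0]) == pytest.approx(expected_d, rel=1e-12)
        assert float(row["yll"].iloc[0]) == pytest.approx(expected_yll, rel=1e-12)
        assert float(row["lle"].iloc[0]) == pytest.approx(
            loss_of_life_expectancy(expected_yll, float(counts.sum()),
                                    bundle.mortality.le0), rel=1e-12)

    def test_national_yll_matches_loop_oracle(self, small_bundle):
        """Vectorised national YLL equals an independent per-stratum loop."""
        bundle = small_bundle
        year = bundle.config.years[0]
        res = compute_burden(bundle.exposure, bundle.population, bundle.mortality,
                             bundle.erf_set, years=[year])
        grouped = curves_by_pollutant(bundle.erf_set)
        rates = bundle.mortality.rates.to_dict()          # {cause: {stratum: B}}
        le = bundle.mortality.le.to_dict()
        counts = bundle.population[year].counts
        strata = list(counts.columns)
        count_rows = counts.to_numpy()
        oracle = 0.0
        for pol, conc_series in (
                ("pm25", bundle.exposure[year].pm25_annual),
                ("o3", bundle.exposure[year].o3_peak_season)):
            conc = conc_series.to_numpy()
            for cause, curves in grouped[pol].items():
                by_band = {cv.age_band: cv for cv in curves}
                for i in range(conc.size):
                    c = float(conc[i])
                    for j, (sex, band, rez) in enumerate(strata):
                        cv = by_band.get(band) or by_band["all"]
                        af = attributable_fraction(relative_risk(cv, c))
                        b = rates[cause][(sex, band, rez)]
                        oracle += af * b * count_rows[i, j] * le[band]
        total = res.national["yll"].sum()
        assert total == pytest.approx(oracle, rel=1e-9)

    def test_raising_pm25_never_lowers_national_yll(self, small_bundle):
        bundle = small_bundle
        year = bundle.config.years[0]
        base = compute_burden(bundle.exposure, bundle.population, bundle.mortality,
                              bundle.erf_set, years=[year], pollutants=("pm25",))
        bumped_grid = type(bundle.exposure[year])(
            year=year,
            pm25_annual=bundle.exposure[year].pm25_annual
            + pd.Series(np.eye(1, len(bundle.exposure[year].pm25_annual), 5)[0] * 30.0,
                        index=bundle.exposure[year].pm25_annual.index),
            o3_monthly=bundle.exposure[year].o3_monthly)
        bumped = compute_burden({year: bumped_grid}, bundle.population,
                                bundle.mortality, bundle.erf_set,
                                years=[year], pollutants=("pm25",))
        assert bumped.national["yll"].sum() >= base.national["yll"].sum()

    def test_deaths_bounded_by_baseline_deaths(self, small_bundle):
        """Attributable deaths per subgroup never exceed total deaths B*P."""
        bundle = small_bundle
        year = bundle.config.years[0]
        res = compute_burden(bundle.exposure, bundle.population, bundle.mortality,
                             bundle.erf_set, years=[year], pollutants=("pm25",))
        per_sub = res.national.groupby(["sex", "age_band", "residence"])["deaths"].sum()
        pop_sub = bundle.population[year].subgroup_totals()
        baseline = bundle.mortality.all_cause.reindex(pop_sub.index) * pop_sub
        joined = pd.concat([per_sub, baseline.rename("max")], axis=1)
        assert (joined["deaths"] <= joined["max"] + 1e-9).all()

    def test_missing_curve_for_requested_cause_errors(self, small_bundle):
        with pytest.raises(ComputationError, match="no exposure-response curve"):
            compute_burden(small_bundle.exposure, small_bundle.population,
                           small_bundle.mortality, small_bundle.erf_set,
                           causes={"pm25": ["asthma"], "o3": []})

    def test_draw_selection_changes_result(self, small_bundle):
        year = small_bundle.config.years[0]
        a = compute_burden(small_bundle.exposure, small_bundle.population,
                           small_bundle.mortality, small_bundle.erf_set,
                           years=[year], draw=0)
        b = compute_burden(small_bundle.exposure, small_bundle.population,
                           small_bundle.mortality, small_bundle.erf_set,
                           years=[year], draw=1)
        assert a.national["deaths"].sum() != b.national["deaths"].sum()
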