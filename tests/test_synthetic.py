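"""Generator contracts: determinism, conservation, structure, recovery."""

import json

import numpy as np
import pandas as pd
import pytest

from airburden import (ConfigurationError, ERFFamily, ScenarioConfig,
                       StageChange, generate_erf_draws,
                       generate_exposure_history, generate_mortality,
                       generate_population, make_scenario,
                       population_weighted_mean, relative_risk)


def no_change_config(**kw):
    defaults = dict(
        n_rows=10, n_cols=10, pm25_baseline_sd=0.0, o3_baseline_sd=0.0,
        pm25_stage_reductions=(StageChange(0.0), StageChange(0.0)),
        o3_stage_deltas=(StageChange(0.0), StageChange(0.0)), seed=3)
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestExposureGenerator:
    def test_zero_change_scenario_has_identical_years(self):
        grids = generate_exposure_history(no_change_config())
        years = sorted(grids)
        for y in years[1:]:
            pd.testing.assert_series_equal(grids[years[0]].pm25_annual,
                                           grids[y].pm25_annual)
            pd.testing.assert_frame_equal(grids[years[0]].o3_monthly,
                                          grids[y].o3_monthly)

    def test_same_seed_gives_identical_fields(self, small_config):
        a = generate_exposure_history(small_config)
        b = generate_exposure_history(small_config)
        for y in a:
            assert (a[y].pm25_annual.to_numpy() == b[y].pm25_annual.to_numpy()).all()
            assert (a[y].o3_monthly.to_numpy() == b[y].o3_monthly.to_numpy()).all()

    def test_different_seeds_differ(self, small_config):
        other = ScenarioConfig(**{**small_config.to_dict(), "seed": 99})
        a = generate_exposure_history(small_config)
        b = generate_exposure_history(other)
        y = small_config.years[0]
        assert not np.allclose(a[y].pm25_annual, b[y].pm25_annual)

    def test_configured_decline_is_recovered_from_fields(self):
        """Population-weighted stage decline matches the generating fraction."""
        cfg = ScenarioConfig(
            n_rows=100, n_cols=100, years=(2013, 2017),
            pm25_stage_reductions=(StageChange(0.30, 0.25),),
            o3_stage_deltas=(StageChange(0.0),), seed=5)
        grids = generate_exposure_history(cfg)
        pop = generate_population(cfg)
        w = pop[2013].cell_totals
        pw13 = population_weighted_mean(grids[2013].pm25_annual, w)
        pw17 = population_weighted_mean(grids[2017].pm25_annual, w)
        realized = 1.0 - pw17 / pw13
        assert realized == pytest.approx(0.30, abs=0.03)

    def test_fields_nonnegative_and_autocorrelated(self, small_bundle, small_config):
        y = small_config.years[0]
        pm = small_bundle.exposure[y].pm25_annual.to_numpy()
        assert (pm >= 0).all()
        field = pm.reshape(small_config.n_rows, small_config.n_cols)
        lag1 = np.corrcoef(field[:, :-1].ravel(), field[:, 1:].ravel())[0, 1]
        assert lag1 > 0.5  # smooth field: strong neighbour correlation

    def test_o3_monthly_share_same_seasonal_shape(self, small_bundle, small_config):
        # every cell's monthly series is its peak-season level times one
        # common summer-peaking seasonal profile
        y = small_config.years[0]
        grid = small_bundle.exposure[y]
        peak = grid.o3_peak_season.to_numpy()
        shape = grid.o3_monthly.to_numpy() / peak[:, None]
        assert np.allclose(shape, shape[0], rtol=1e-9)
        assert shape[0].argmax() in (6, 7)  # peaks mid-summer

    def test_nonpositive_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(n_rows=0)


class TestPopulationGenerator:
    def test_zero_aging_freezes_subgroup_shares(self):
        cfg = no_change_config(aging_rate=0.0)
        pops = generate_population(cfg)
        years = sorted(pops)
        s0 = pops[years[0]].counts / cfg.total_population
        for y in years[1:]:
            pd.testing.assert_frame_equal(s0, pops[y].counts / cfg.total_population)

    def test_subgroup_shares_sum_to_one_per_cell(self, small_bundle):
        for pop in small_bundle.population.values():
            shares = pop.counts.div(pop.cell_totals, axis=0)
            assert np.allclose(shares.sum(axis=1), 1.0, atol=1e-12)

    def test_population_total_conserved(self, small_bundle, small_config):
        for pop in small_bundle.population.values():
            assert pop.total == pytest.approx(small_config.total_population,
                                              rel=5e-3)

    def test_aging_increases_mean_age(self, small_bundle, small_config):
        mids = np.array([lo + 5.0 if hi is None else 0.5 * (lo + hi)
                         for lo, hi in small_config.age_bands])
        mean_ages = []
        for y in small_config.years:
            by_band = small_bundle.population[y].subgroup_totals().groupby("age_band").sum()
            by_band = by_band.reindex(small_config.band_labels)
            mean_ages.append(float((by_band.to_numpy() * mids).sum() / by_band.sum()))
        assert all(a < b for a, b in zip(mean_ages, mean_ages[1:]))

    def test_empty_age_bands_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(age_bands=())


class TestMortalityGenerator:
    def test_rates_increase_and_le_decreases_with_age(self, small_config):
        sched = generate_mortality(small_config)
        labels = small_config.band_labels
        young = sched.all_cause.xs(("male", labels[0]), level=("sex", "age_band"))
        old = sched.all_cause.xs(("male", labels[-1]), level=("sex", "age_band"))
        assert (old.to_numpy() > young.to_numpy()).all()
        assert (np.diff(sched.le.to_numpy()) < 0).all()

    def test_cause_rates_conserve_all_cause_total(self, small_config):
        sched = generate_mortality(small_config)
        recomputed = sched.rates.sum(axis=1)
        assert np.allclose(recomputed, sched.all_cause, rtol=0, atol=1e-12)

    def test_bad_cause_profile_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            generate_mortality(small_config, cause_profile={"a": 0.5, "b": 0.4})


class TestERFDraws:
    FAMILY = ERFFamily("pm25", "ischemic_heart_disease", "all",
                       alpha=0.6, beta=0.18, gamma=0.55, tmrel=4.15)

    def test_zero_noise_draws_equal_central(self):
        cv = generate_erf_draws(self.FAMILY, n_draws=5, noise_scale=0.0, seed=1)
        for d in range(5):
            assert (cv.rr_draws[:, d] == cv.rr_central).all()

    def test_rr_is_one_at_tmrel_for_every_draw(self):
        cv = generate_erf_draws(self.FAMILY, n_draws=6, noise_scale=0.2, seed=2)
        for d in range(6):
            assert relative_risk(cv, self.FAMILY.tmrel, draw=d) == pytest.approx(1.0)

    def test_sublinear_family_has_decreasing_marginal_rr(self):
        fam = ERFFamily("pm25", "x", "all", alpha=0.8, beta=0.05, gamma=0.7,
                        tmrel=5.0)
        cv = generate_erf_draws(fam, n_draws=1, noise_scale=0.0, seed=0)
        above = cv.conc > fam.tmrel + 1
        increments = np.diff(cv.rr_central[above])
        assert (np.diff(increments) < 1e-12).all()

    def test_draws_monotone_and_at_least_one(self):
        cv = generate_erf_draws(self.FAMILY, n_draws=10, noise_scale=0.3, seed=3)
        assert (np.diff(cv.rr_draws, axis=0) >= 0).all()
        assert (cv.rr_draws >= 1.0).all()
        with pytest.raises(ConfigurationError):
            generate_erf_draws(self.FAMILY, n_draws=0, noise_scale=0.1, seed=3)
        with pytest.raises(ConfigurationError):
            generate_erf_draws(self.FAMILY, n_draws=2, noise_scale=-0.1, seed=3)


class TestBundle:
    def test_bundle_is_seed_deterministic(self, small_config, small_bundle):
        again = make_scenario(small_config, n_draws=8)
        y = small_config.years[-1]
        assert (again.exposure[y].pm25_annual.to_numpy()
                == small_bundle.exposure[y].pm25_annual.to_numpy()).all()
        assert (again.population[y].counts.to_numpy()
                == small_bundle.population[y].counts.to_numpy()).all()
        assert (again.erf_set[0].rr_draws == small_bundle.erf_set[0].rr_draws).all()

    def test_truth_round_trips_through_json(self, small_bundle, tmp_path):
        path = tmp_path / "truth.json"
        path.write_text(json.dumps(small_bundle.truth))
        assert json.loads(path.read_text()) == small_bundle.truth
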