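"""Synthetic scene generator: determinism, structure, recoverable truth."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from vegdyn.fvc import annual_mean_evi, monthly_composite
from vegdyn.grid import GridStack
from vegdyn.synthetic import (CategoricalParams, ClimateParams, DemParams,
                              EviParams, SceneConfig, generate_categorical,
                              generate_climate, generate_dem,
                              generate_evi_series, generate_pls_dataset,
                              generate_scene)
from vegdyn.trend import theil_sen_slope


@pytest.fixture(scope="module")
def small_config():
    return SceneConfig(shape=(40, 40), seed=7)


class TestDem:
    def test_deterministic_under_seed(self, small_config):
        a = generate_dem(small_config)
        b = generate_dem(small_config)
        assert np.array_equal(a.values, b.values)

    def test_zero_relief_is_planar_ramp(self):
        cfg = SceneConfig(shape=(20, 20), seed=1,
                          dem_params=DemParams(relief_amplitude_m=0.0))
        dem = generate_dem(cfg)
        # second differences of a plane vanish along both axes
        assert np.allclose(np.diff(dem.values, n=2, axis=0), 0.0, atol=1e-9)
        assert np.allclose(np.diff(dem.values, n=2, axis=1), 0.0, atol=1e-9)
        # high corner is the northwest
        assert dem.values[0, 0] == dem.values.max()

    def test_elevation_within_clip_range(self, small_config):
        dem = generate_dem(small_config)
        lo, hi = small_config.dem_params.elevation_range_m
        assert dem.values.min() >= lo and dem.values.max() <= hi


class TestClimate:
    def test_lapse_rate_recovered_from_mean_difference(self):
        cfg = SceneConfig(shape=(30, 30), seed=2, years=(2001, 2022))
        dem = generate_dem(cfg)
        t, _ = generate_climate(dem, cfg)
        tbar = np.mean([g.values for g in t.grids], axis=0)
        flat_e = dem.values.ravel()
        flat_t = tbar.ravel()
        fit = np.polyfit(flat_e, flat_t, 1)
        assert fit[0] == pytest.approx(-cfg.climate_params.lapse_c_per_m,
                                       rel=0.05)

    def test_noise_free_relations_exact_and_precip_nonnegative(self):
        cp = ClimateParams(t_interannual_sd_c=0.0, t_noise_sd_c=0.0,
                           p_interannual_sd_mm=0.0, p_noise_sd_mm=0.0)
        cfg = SceneConfig(shape=(10, 10), seed=3, climate_params=cp)
        dem = generate_dem(cfg)
        t, p = generate_climate(dem, cfg)
        expected = cp.t_sea_level_c - cp.lapse_c_per_m * dem.values
        assert np.allclose(t.grids[0].values, expected)
        assert np.allclose(t.grids[0].values, t.grids[-1].values)
        for g in p.grids:
            assert g.values.min() >= 0.0


class TestCategorical:
    def test_every_class_present_with_roughly_equal_shares(self):
        cfg = SceneConfig(shape=(100, 100), seed=4)
        cg = generate_categorical(cfg, 4)
        counts = np.bincount(cg.grid.values.ravel())[1:]
        assert len(counts) == 4 and counts.min() > 0
        shares = counts / counts.sum()
        assert np.all(np.abs(shares - 0.25) < 0.05)

    def test_deterministic_and_offset_independent(self):
        cfg = SceneConfig(shape=(30, 30), seed=5)
        a = generate_categorical(cfg, 3, seed_offset=0)
        b = generate_categorical(cfg, 3, seed_offset=0)
        c = generate_categorical(cfg, 3, seed_offset=1)
        assert np.array_equal(a.grid.values, b.grid.values)
        assert not np.array_equal(a.grid.values, c.grid.values)

    def test_too_many_classes_rejected(self):
        cfg = SceneConfig(shape=(3, 3), seed=0)
        with pytest.raises(ValueError):
            generate_categorical(cfg, 10)


def annual_series(scene, config):
    monthly = monthly_composite(scene.evi_monthly)
    years = config.year_list
    return GridStack([annual_mean_evi(monthly, y) for y in years],
                     [(y,) for y in years])


class TestEvi:
    def quiet_params(self, **kw):
        base = dict(landuse_effect_sd=0.0, trend_improve=0.0,
                    trend_degrade=0.0, temperature_coeff=0.0,
                    precipitation_coeff=0.0, noise_sd=0.0)
        base.update(kw)
        return EviParams(**base)

    def test_degenerate_config_constant_annual_means(self):
        cfg = SceneConfig(shape=(12, 12), seed=6, evi_params=self.quiet_params())
        scene = generate_scene(cfg)
        annual = annual_series(scene, cfg)
        cube = np.stack([g.values for g in annual.grids])
        assert np.allclose(cube, cube[0], atol=1e-12)

    def test_planted_linear_trend_recovered_exactly_without_noise(self):
        cfg = SceneConfig(shape=(12, 12), seed=6,
                          evi_params=self.quiet_params(trend_improve=0.002))
        scene = generate_scene(cfg)
        annual = annual_series(scene, cfg)
        cube = np.stack([g.values for g in annual.grids])
        tau = scene.truth["trend"].values
        r, c = np.argwhere(tau == 0.002)[0]
        assert theil_sen_slope(cube[:, r, c]) == pytest.approx(0.002, abs=1e-12)

    def test_noisy_trend_recovery_within_half_slope_threshold(self):
        cfg = SceneConfig(shape=(25, 25), seed=8,
                          evi_params=self.quiet_params(trend_improve=0.002,
                                                       noise_sd=0.02))
        scene = generate_scene(cfg)
        annual = annual_series(scene, cfg)
        cube = np.stack([g.values for g in annual.grids])
        tau = scene.truth["trend"].values
        cells = np.argwhere(tau == 0.002)
        assert len(cells) >= 100
        slopes = [theil_sen_slope(cube[:, r, c]) for r, c in cells]
        assert np.mean(slopes) == pytest.approx(0.002, abs=0.0005)

    def test_sixteen_day_mode_doubles_layers(self):
        cfg = SceneConfig(shape=(8, 8), seed=9,
                          evi_params=EviParams(periods_per_month=2))
        scene = generate_scene(cfg)
        n_years = len(cfg.year_list)
        assert len(scene.evi_monthly) == n_years * 12 * 2
        assert len(monthly_composite(scene.evi_monthly)) == n_years * 12

    def test_evi_bounded(self, small_config):
        scene = generate_scene(small_config)
        for g in scene.evi_monthly.grids[:24]:
            assert g.values.min() >= 0.0 and g.values.max() <= 1.0


class TestScene:
    def test_bundle_complete_and_coregistered(self, small_config):
        scene = generate_scene(small_config)
        layers = [scene.dem, scene.slope, scene.aspect, scene.soc,
                  scene.grazing, scene.popdensity, scene.landuse.grid,
                  scene.soil_type.grid]
        for layer in layers:
            assert layer.same_geometry(scene.dem)
        for key in ("trend", "baseline", "class_effects",
                    "temperature_coeff", "precipitation_coeff"):
            assert key in scene.truth

    def test_different_seeds_differ(self, small_config):
        other = replace(small_config, seed=small_config.seed + 1)
        a = generate_scene(small_config)
        b = generate_scene(other)
        diff = np.abs(a.evi_monthly.grids[0].values
                      - b.evi_monthly.grids[0].values)
        assert diff.max() > 0


class TestPlsGenerator:
    def test_latent_correlations_match_implied(self, rng):
        paths = {("A", "B"): 0.5, ("B", "C"): -0.4}
        data, truth = generate_pls_dataset(paths, {"A": 1, "B": 1, "C": 1},
                                           n=200000, seed=12)
        # single-indicator blocks: indicators are the latents
        emp = np.corrcoef(data.to_numpy(), rowvar=False)
        assert emp[0, 1] == pytest.approx(0.5, abs=0.01)
        assert emp[1, 2] == pytest.approx(-0.4, abs=0.01)
        assert emp[0, 2] == pytest.approx(0.5 * -0.4, abs=0.01)

    def test_infeasible_structure_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            generate_pls_dataset({("A", "B"): 0.8, ("C", "B"): 0.8,
                                  ("A", "C"): 0.9}, {"A": 1, "B": 1, "C": 1})
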