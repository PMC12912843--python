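"""Synthetic scene/survey generator: determinism, structure, recovery oracles."""

import datetime

import numpy as np
import pytest

from lakefcc import ConfigurationError, SceneConfig, synth


JULY15 = datetime.date(2020, 7, 15)


class TestGenerateScene:
    def test_zero_noise_zero_cloud_reproduces_truth(self, clean_config):
        scene, truth = synth.generate_scene(clean_config, JULY15)
        w = scene.water
        np.testing.assert_allclose(scene.chl[w], truth.true_chl[w])
        assert (scene.flags[w] == 0).all()

    def test_full_cloud_flags_every_water_cell(self, clean_config):
        cfg = SceneConfig(**{**clean_config.__dict__, "cloud_fraction": 1.0})
        scene, _ = synth.generate_scene(cfg, JULY15)
        assert (scene.flags[scene.water] != 0).all()

    def test_fixed_seed_is_bit_identical(self, toy_config):
        a, ta = synth.generate_scene(toy_config, JULY15)
        b, tb = synth.generate_scene(toy_config, JULY15)
        for name in ("chl", "sst", "par", "kd490", "flags", "straylight_pct"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
        np.testing.assert_array_equal(ta.true_pp, tb.true_pp)

    def test_shore_exceeds_centre_every_date(self, toy_config):
        from scipy import ndimage

        for date in (datetime.date(2020, m, 10) for m in (5, 7, 10)):
            _, truth = synth.generate_scene(toy_config, date)
            water = synth.default_lake_geometry(tuple(toy_config.grid_shape))
            dist = ndimage.distance_transform_edt(water)
            shore = water & (dist <= 1.5)
            centre = water & (dist >= np.quantile(dist[water], 0.75))
            assert np.nanmean(truth.true_chl[shore]) > np.nanmean(truth.true_chl[centre])

    def test_sst_within_seasonal_bounds(self, clean_config):
        for month in (5, 7, 10):
            scene, _ = synth.generate_scene(clean_config, datetime.date(2020, month, 15))
            vals = scene.sst[scene.water]
            assert vals.min() >= 0.0 and vals.max() <= 25.0

    def test_off_season_date_rejected(self, toy_config):
        with pytest.raises(ConfigurationError):
            synth.generate_scene(toy_config, datetime.date(2020, 1, 15))

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="chl_base"):
            SceneConfig(chl_base=-1.0)
        with pytest.raises(ConfigurationError, match="cloud_fraction"):
            SceneConfig(cloud_fraction=1.5)

    def test_kd490_positive_on_water(self, toy_config):
        scene, _ = synth.generate_scene(toy_config, JULY15)
        assert (scene.kd490[scene.water] > 0).all()


class TestGenerateSeries:
    def test_one_scene_per_calendar_day(self, toy_config):
        scenes, truths, counts = synth.generate_series(toy_config, [2021], [6])
        assert len(scenes) == 30 and len(truths) == 30
        assert (2021, 6) in counts

    def test_seasonal_chl_peak_in_july_august(self, toy_config):
        # the configured seasonal modulation peaks at day-of-year 200 (mid-July)
        doys = np.arange(121, 305)
        season = [synth.seasonal_factor(d, toy_config.season_amplitude) for d in doys]
        peak_doy = doys[int(np.argmax(season))]
        assert 182 <= peak_doy <= 243  # July 1 - Aug 31
        assert peak_doy == 200

    def test_heavy_cloud_defeats_min_valid_days(self, toy_config):
        cfg = SceneConfig(**{**toy_config.__dict__, "cloud_fraction": 0.9})
        _, _, counts = synth.generate_series(cfg, [2021], [6])
        water = synth.default_lake_geometry(tuple(cfg.grid_shape))
        frac_failing = np.mean(counts[(2021, 6)][water] < 5)
        assert frac_failing > 0.8  # binomial expectation: 30 x 0.1 = 3 < 5 valid days

    def test_empty_selection_rejected(self, toy_config):
        with pytest.raises(ConfigurationError):
            synth.generate_series(toy_config, [], [6])
        with pytest.raises(ConfigurationError):
            synth.generate_series(toy_config, [2021], [])


class TestGenerateSurvey:
    def test_zero_cv_recovers_biomass_exactly(self, toy_config):
        dens, gillnet = synth.generate_survey(toy_config, 2021, 5000.0, sampling_cv=0.0)
        recovered = (
            dens["density_ind_per_m3"].mean()
            * gillnet["weight_g"].mean()
            * synth.lake_volume_m3(toy_config)
            * 1e-6
        )
        assert recovered == pytest.approx(5000.0, rel=1e-12)

    def test_fixed_seed_identical_survey(self, toy_config):
        a = synth.generate_survey(toy_config, 2021, 5000.0)
        b = synth.generate_survey(toy_config, 2021, 5000.0)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_monte_carlo_mean_recovery_within_1pct(self, toy_config):
        recs = []
        for i in range(1000):
            cfg = SceneConfig(**{**toy_config.__dict__, "seed": i})
            dens, gillnet = synth.generate_survey(cfg, 2021, 100_000.0, sampling_cv=0.05)
            recs.append(
                dens["density_ind_per_m3"].mean()
                * gillnet["weight_g"].mean()
                * synth.lake_volume_m3(cfg)
                * 1e-6
            )
        assert np.mean(recs) == pytest.approx(100_000.0, rel=0.01)

    def test_lengths_positive_weights_follow_power_law(self, toy_config):
        _, gillnet = synth.generate_survey(toy_config, 2021, 5000.0)
        assert (gillnet["length_cm"] > 0).all()
        np.testing.assert_allclose(
            gillnet["weight_g"], 0.01 * gillnet["length_cm"] ** 3
        )

    def test_nonpositive_biomass_rejected(self, toy_config):
        with pytest.raises(ConfigurationError):
            synth.generate_survey(toy_config, 2021, 0.0)
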