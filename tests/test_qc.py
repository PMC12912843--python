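"""Quality control: masking, filtering, compositing, gap-fill, matchups, RMA fit."""

import datetime

import numpy as np
import pytest

from lakefcc import qc
from lakefcc.scenes import GridScene


def make_scene(chl, water=None, date=datetime.date(2021, 7, 1), **overrides):
    chl = np.asarray(chl, dtype=float)
    shape = chl.shape
    layers = dict(
        chl=chl,
        sst=np.full(shape, 15.0),
        par=np.full(shape, 40.0),
        kd490=np.full(shape, 0.3),
        flags=np.zeros(shape, dtype=int),
        straylight_pct=np.zeros(shape),
        ice=np.zeros(shape, dtype=int),
        water=np.ones(shape, dtype=bool) if water is None else np.asarray(water, bool),
    )
    layers.update(overrides)
    return GridScene(date=date, **layers)


class TestLakeMask:
    def test_identical_scenes_exclude_nothing(self):
        scenes = [make_scene(np.ones((4, 4))) for _ in range(3)]
        mask = qc.build_lake_mask(scenes)
        assert mask.excluded_fraction == 0.0
        assert mask.water.all()

    def test_shrinking_fringe_excluded_fraction(self):
        # 100 ever-wet cells; one scene loses a 10-cell fringe -> 0.10
        full = np.ones((10, 10), dtype=bool)
        shrunk = full.copy()
        shrunk[0, :] = False
        scenes = [make_scene(np.ones((10, 10)), water=full),
                  make_scene(np.ones((10, 10)), water=shrunk)]
        mask = qc.build_lake_mask(scenes)
        assert mask.excluded_fraction == pytest.approx(0.10)
        assert mask.water.sum() == 90

    def test_mask_idempotence(self):
        rng = np.random.default_rng(3)
        scenes = [
            make_scene(np.ones((8, 8)), water=rng.random((8, 8)) > 0.2)
            for _ in range(4)
        ]
        mask = qc.build_lake_mask(scenes)
        remasked = [make_scene(np.ones((8, 8)), water=mask.water) for _ in range(4)]
        mask2 = qc.build_lake_mask(remasked)
        np.testing.assert_array_equal(mask.water, mask2.water)
        assert mask2.excluded_fraction == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            qc.build_lake_mask([])


class TestQualityFilters:
    def test_all_nominal_scene_unchanged(self):
        scene = make_scene(np.full((3, 3), 2.0))
        out, n_valid = qc.apply_quality_filters(scene)
        assert n_valid == 9
        np.testing.assert_array_equal(out.chl, scene.chl)

    def test_full_ice_cover_invalidates_everything(self):
        scene = make_scene(np.full((3, 3), 2.0), ice=np.ones((3, 3), dtype=int))
        out, n_valid = qc.apply_quality_filters(scene)
        assert n_valid == 0
        assert np.isnan(out.chl).all()

    def test_single_straylight_cell_enumerated(self):
        stray = np.zeros((3, 3))
        stray[1, 1] = 6.0
        scene = make_scene(np.full((3, 3), 2.0), straylight_pct=stray)
        out, n_valid = qc.apply_quality_filters(scene)
        assert n_valid == 8
        assert np.isnan(out.chl[1, 1])
        assert np.isfinite(out.chl).sum() == 8


class TestMonthlyComposite:
    def _scenes_with_valid_days(self, chl_by_day, n_days):
        """One 1x1-cell scene per day; chl_by_day gives the valid days' values."""
        scenes = []
        for d in range(1, n_days + 1):
            if d <= len(chl_by_day):
                scenes.append(make_scene([[chl_by_day[d - 1]]],
                                         date=datetime.date(2021, 6, d)))
            else:
                scenes.append(make_scene([[1.0]], date=datetime.date(2021, 6, d),
                                         flags=np.ones((1, 1), dtype=int)))
        return scenes

    def test_four_valid_days_is_missing(self):
        scenes = self._scenes_with_valid_days([1, 2, 3, 4], 10)
        mask = qc.build_lake_mask(scenes)
        comp = qc.monthly_composite(scenes, mask)
        assert comp.valid_days[0, 0] == 4
        assert np.isnan(comp.chl[0, 0])

    def test_five_valid_days_mean(self):
        scenes = self._scenes_with_valid_days([1, 2, 3, 4, 6], 10)
        mask = qc.build_lake_mask(scenes)
        comp = qc.monthly_composite(scenes, mask)
        assert comp.chl[0, 0] == pytest.approx(3.2)

    def test_single_scene_identity_with_threshold_one(self):
        scene = make_scene(np.array([[1.5, 2.5], [0.5, 3.5]]))
        mask = qc.build_lake_mask([scene])
        comp = qc.monthly_composite([scene], mask, min_valid_days=1)
        np.testing.assert_allclose(comp.chl, scene.chl)

    def test_scenes_spanning_months_rejected(self):
        scenes = [make_scene([[1.0]], date=datetime.date(2021, 6, 30)),
                  make_scene([[1.0]], date=datetime.date(2021, 7, 1))]
        mask = qc.build_lake_mask(scenes)
        with pytest.raises(ValueError, match="month"):
            qc.monthly_composite(scenes, mask)

    def test_defined_iff_enough_days_or_filled(self):
        scenes = self._scenes_with_valid_days([1, 2, 3, 4, 6], 10)
        mask = qc.build_lake_mask(scenes)
        comp = qc.monthly_composite(scenes, mask)
        defined = np.isfinite(comp.chl)
        np.testing.assert_array_equal(
            defined, (comp.valid_days >= 5) ^ comp.filled
        )


def _composite(year, month, chl):
    chl = np.asarray(chl, dtype=float)
    return qc.MonthlyComposite(
        year=year, month=month, chl=chl,
        sst=np.where(np.isfinite(chl), 15.0, np.nan),
        par=np.where(np.isfinite(chl), 40.0, np.nan),
        kd490=np.where(np.isfinite(chl), 0.3, np.nan),
        valid_days=np.where(np.isfinite(chl), 10, 0).astype(int),
        filled=np.zeros(chl.shape, dtype=bool),
    )


class TestGapFill:
    def test_midpoint_interpolation(self):
        series = [_composite(2021, m, [[v]]) for m, v in ((5, 10.0), (6, np.nan), (7, 20.0))]
        out = qc.gap_fill(series, max_missing_fraction=0.5)
        assert out[1].chl[0, 0] == pytest.approx(15.0)
        assert out[1].filled[0, 0]

    def test_exceeding_missing_fraction_not_filled(self):
        vals = [10.0] * 12
        vals[5] = np.nan
        vals[8] = np.nan  # 2/12 = 16.7% >= 10%
        series = [_composite(2021, 1, [[v]]) for v in vals]
        for i, c in enumerate(series):
            c.month = i + 1
        out = qc.gap_fill(series, max_missing_fraction=0.10)
        assert np.isnan(out[5].chl[0, 0]) and np.isnan(out[8].chl[0, 0])

    def test_no_gaps_series_unchanged(self):
        series = [_composite(2021, m, [[float(m)]]) for m in range(5, 11)]
        out = qc.gap_fill(series)
        for a, b in zip(series, out):
            np.testing.assert_array_equal(a.chl, b.chl)
            assert not b.filled.any()

    def test_leading_trailing_gaps_never_extrapolated(self):
        series = [_composite(2021, m, [[v]])
                  for m, v in ((5, np.nan), (6, 10.0), (7, 20.0), (8, 30.0),
                               (9, 40.0), (10, 50.0), (11, 60.0), (12, np.nan))]
        out = qc.gap_fill(series, max_missing_fraction=0.5)
        assert np.isnan(out[0].chl[0, 0]) and np.isnan(out[-1].chl[0, 0])

    def test_exact_for_linear_trend(self):
        vals = [10.0, 20.0, np.nan, 40.0, 50.0, np.nan, 70.0, 80.0, 90.0, 100.0, 110.0]
        series = [_composite(2021, m + 1, [[v]]) for m, v in enumerate(vals)]
        out = qc.gap_fill(series, max_missing_fraction=0.25)
        got = [c.chl[0, 0] for c in out]
        np.testing.assert_allclose(got, 10.0 * np.arange(1, 12))


class TestMatchups:
    def test_single_cell_box(self):
        scene = make_scene(np.arange(9, dtype=float).reshape(3, 3))
        m = qc.extract_matchup(scene, 1, 1, field_value=4.5, time_offset_h=2.0)
        assert m.satellite_value == 4.0
        assert m.valid

    def test_offset_beyond_12h_invalid(self):
        scene = make_scene(np.full((3, 3), 2.0))
        m = qc.extract_matchup(scene, 1, 1, field_value=2.0, time_offset_h=13.0)
        assert not m.valid

    def test_heterogeneous_box_fails_sd_rule(self):
        scene = make_scene(np.array([[1.0, 2.0, 100.0]]))
        m = qc.extract_matchup(scene, 0, 1, field_value=2.0, time_offset_h=0.0, box_size=3)
        assert m.satellite_value == 2.0  # median of {1, 2, 100}
        assert m.box_sd_over_mean > 0.2
        assert not m.valid

    def test_station_outside_grid_rejected(self):
        scene = make_scene(np.full((3, 3), 2.0))
        with pytest.raises(ValueError, match="outside"):
            qc.extract_matchup(scene, 5, 1, field_value=2.0, time_offset_h=0.0)


def _pairs(x, y):
    return [
        qc.MatchupPair(station_id=str(i), variable_name="chl", satellite_value=xi,
                       field_value=yi, time_offset_h=0.0, box_sd_over_mean=0.0, valid=True)
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


class TestChlaCorrection:
    def test_identity_data_gives_identity_model(self):
        x = np.array([0.5, 1.0, 2.0, 3.0])
        model = qc.fit_chla_correction(_pairs(x, x))
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_data_recovered(self):
        x = np.array([0.5, 1.0, 2.0, 4.0])
        model = qc.fit_chla_correction(_pairs(x, 0.5 * x + 1.0))
        assert model.slope == pytest.approx(0.5)
        assert model.intercept == pytest.approx(1.0)

    def test_noisy_recovery_within_10pct(self, rng):
        x = rng.uniform(0.5, 5.0, size=57)
        y = (0.6 * x + 0.8) * (1.0 + 0.05 * rng.standard_normal(57))
        model = qc.fit_chla_correction(_pairs(x, y))
        assert model.slope == pytest.approx(0.6, rel=0.10)
        assert model.intercept == pytest.approx(0.8, rel=0.10)
        assert model.n_fit == 57

    def test_rma_symmetric_under_axis_exchange(self, rng):
        x = rng.uniform(0.5, 5.0, size=30)
        y = 2.0 * x + rng.normal(0, 0.3, size=30)
        fwd = qc.fit_chla_correction(_pairs(x, y)).slope
        rev = qc.fit_chla_correction(_pairs(y, x)).slope
        assert fwd == pytest.approx(1.0 / rev)

    def test_correction_reduces_are_on_fit_set(self, rng):
        from lakefcc.metrics import compare

        x = rng.uniform(0.5, 5.0, size=40)
        y = 0.6 * x + 0.2 + rng.normal(0, 0.05, size=40)  # satellite overestimates
        model = qc.fit_chla_correction(_pairs(x, y))
        raw = abs(compare(x, y).are_pct)
        corrected = abs(compare(qc.apply_chla_correction(x, model), y).are_pct)
        assert corrected < raw

    def test_too_few_or_degenerate_matchups_rejected(self):
        with pytest.raises(ValueError):
            qc.fit_chla_correction(_pairs([1.0, 2.0], [1.0, 2.0]))
        with pytest.raises(ValueError):
            qc.fit_chla_correction(_pairs([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_apply_correction_arithmetic_and_clip(self):
        model = qc.CorrectionModel(slope=0.5, intercept=1.0, n_fit=10)
        assert qc.apply_chla_correction(4.0, model) == 3.0
        identity = qc.CorrectionModel(slope=1.0, intercept=0.0, n_fit=10)
        np.testing.assert_array_equal(
            qc.apply_chla_correction(np.array([1.0, 2.0]), identity), [1.0, 2.0]
        )
        negative = qc.CorrectionModel(slope=1.0, intercept=-5.0, n_fit=10)
        assert qc.apply_chla_correction(2.0, negative) == 0.0

    def test_chronological_split(self):
        pairs = _pairs(np.arange(10.0), np.arange(10.0))
        fit, val = qc.split_matchups(pairs, fit_fraction=0.6)
        assert len(fit) == 6 and len(val) == 4
        assert fit[0].station_id == "0" and val[0].station_id == "6"
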