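"""Appraisal: weights, band pooling, circumplex geometry, cadence."""

import math

import numpy as np
import pytest

from soniclimate.appraisal import (appraise_second, appraise_series,
                                   band_audibility, contribution_weight,
                                   n_seconds_for_duration)
from soniclimate.config import default_config
from soniclimate.errors import InvalidConfigError, InvalidInputError

S = 1.0 / math.sqrt(2.0)
TAUS = (1.0, 10.0, 100.0)


class TestContributionWeight:
    @pytest.mark.parametrize("value,rng,expected", [
        (0.0, (0.0, 15.0), 0.0),
        (15.0, (0.0, 15.0), 1.0),
        (50.0, (30.0, 70.0), 0.5),
        (-5.0, (0.0, 15.0), 0.0),   # clipped below
        (99.0, (0.0, 15.0), 1.0),   # clipped above
    ])
    def test_linear_scaling_with_clipping(self, value, rng, expected):
        assert contribution_weight(value, rng) == pytest.approx(expected)

    def test_degenerate_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            contribution_weight(1.0, (5.0, 5.0))


class TestBandAudibility:
    def test_silent_layer_gives_zero(self, center_freqs):
        mat = np.zeros((100, center_freqs.shape[0]))
        assert band_audibility(mat, center_freqs, (20, 23000), t=2,
                               scope=1.0, frame_rate=20.0) == 0.0

    def test_single_active_cell_pools_to_its_value(self, center_freqs):
        # 90th-percentile pooling runs over active frames only, so one
        # 12 dB cell inside band and scope is reported as 12 dB
        mat = np.zeros((100, center_freqs.shape[0]))
        k = int(np.argmin(np.abs(center_freqs - 4000)))
        mat[45, k] = 12.0
        val = band_audibility(mat, center_freqs, (3000, 8000), t=2,
                              scope=5.0, frame_rate=20.0)
        assert val == pytest.approx(12.0)

    def test_matches_bruteforce_pooling(self, center_freqs):
        rng = np.random.default_rng(4)
        mat = np.clip(rng.normal(2, 4, size=(200, center_freqs.shape[0])),
                      0, None)
        band, scope, fr, t = (500.0, 4000.0), 3.0, 20.0, 7
        val = band_audibility(mat, center_freqs, band, t, scope, fr)
        mask = (center_freqs >= band[0]) & (center_freqs < band[1])
        win = mat[int((t + 1 - scope) * fr):int((t + 1) * fr)][:, mask]
        fm = win.max(axis=1)
        expected = np.percentile(fm[fm > 0], 90.0)
        assert val == pytest.approx(expected)

    def test_band_without_channels_rejected(self, center_freqs):
        mat = np.zeros((40, center_freqs.shape[0]))
        with pytest.raises(InvalidConfigError):
            band_audibility(mat, center_freqs, (1.0, 2.0), t=0,
                            scope=1.0, frame_rate=20.0)


class TestAppraiseSecond:
    def cfg(self):
        return default_config(taus=TAUS)

    def test_silence_maps_to_origin(self, make_layerset):
        frame = appraise_second(make_layerset(), self.cfg(), t=3)
        assert (frame.pleasantness, frame.eventfulness) == (0.0, 0.0)

    def test_saturated_minute_foreground_on_chaotic_diagonal(self, make_layerset):
        ls = make_layerset(minute_fg=np.full((200, 64), 20.0))
        frame = appraise_second(ls, self.cfg(), t=3)
        assert frame.pleasantness == pytest.approx(-S)
        assert frame.eventfulness == pytest.approx(S)

    def test_saturated_high_band_second_fg_is_calm(self, make_layerset,
                                                   center_freqs):
        mat = np.zeros((200, 64))
        mat[:, center_freqs >= 2300] = 25.0
        frame = appraise_second(make_layerset(second_fg=mat), self.cfg(), t=3)
        assert frame.pleasantness == pytest.approx(S)
        assert frame.eventfulness == pytest.approx(-S)

    def test_saturated_low_band_second_fg_is_lively(self, make_layerset,
                                                    center_freqs):
        mat = np.zeros((200, 64))
        mat[:, center_freqs < 2300] = 25.0
        frame = appraise_second(make_layerset(second_fg=mat), self.cfg(), t=3)
        assert frame.pleasantness == pytest.approx(S)
        assert frame.eventfulness == pytest.approx(S)

    def test_loud_hour_background_is_boring(self, make_layerset):
        ls = make_layerset(hour_bg=np.full((200, 64), -20.0))
        frame = appraise_second(ls, self.cfg(), t=3)
        assert frame.pleasantness == pytest.approx(-S)
        assert frame.eventfulness == pytest.approx(-S)

    def test_center_rows_damp_to_origin(self, make_layerset, center_freqs):
        # hour-foreground high band maps to "center": zero pull at any level
        mat = np.zeros((200, 64))
        mat[:, center_freqs >= 2300] = 40.0
        frame = appraise_second(make_layerset(hour_fg=mat), self.cfg(), t=3)
        assert (frame.pleasantness, frame.eventfulness) == (0.0, 0.0)
        assert frame.contributions.max() == 1.0

    def test_weak_single_row_scales_proportionally(self, make_layerset):
        ls = make_layerset(minute_fg=np.full((200, 64), 7.5))
        frame = appraise_second(ls, self.cfg(), t=3)
        assert frame.magnitude == pytest.approx(0.5)

    def test_out_of_range_second_rejected(self, make_layerset):
        with pytest.raises(InvalidInputError):
            appraise_second(make_layerset(), self.cfg(), t=100)

    def test_increasing_chaotic_row_never_raises_pleasantness(self,
                                                              make_layerset):
        prev_p, prev_e = 2.0, -2.0
        for aud in np.linspace(0, 20, 9):
            ls = make_layerset(minute_fg=np.full((200, 64), aud),
                               second_fg=np.full((200, 64), 6.0))
            frame = appraise_second(ls, self.cfg(), t=3)
            assert frame.pleasantness <= prev_p + 1e-12
            assert frame.eventfulness >= prev_e - 1e-12
            prev_p, prev_e = frame.pleasantness, frame.eventfulness


class TestAppraiseSeries:
    def test_one_frame_per_second(self, mixed_scene):
        series = mixed_scene["series"]
        assert len(series) == 120
        assert np.array_equal(series.t, np.arange(120))

    def test_all_frames_inside_unit_disk(self, mixed_scene):
        series = mixed_scene["series"]
        radius = series.pleasantness ** 2 + series.eventfulness ** 2
        assert radius.max() <= 1.0 + 1e-12

    def test_full_day_cadence_analytic(self):
        assert n_seconds_for_duration(86400.0, frame_rate=50.0) == 86400
        assert n_seconds_for_duration(60.0, frame_rate=50.0) == 60

    def test_bird_segment_calm_passage_chaotic(self, mixed_scene):
        series = mixed_scene["series"]
        p, e = series.pleasantness, series.eventfulness
        bird, car = mixed_scene["bird_seconds"], mixed_scene["car_seconds"]
        assert ((p[bird] > 0) & (e[bird] < 0)).mean() > 0.5
        assert ((p[car] < 0) & (e[car] > 0)).mean() > 0.5

    def test_csv_roundtrip(self, mixed_scene, tmp_path):
        series = mixed_scene["series"]
        path = tmp_path / "series.csv"
        series.to_csv(path)
        back = type(series).from_csv(path, series.config)
        np.testing.assert_allclose(back.pleasantness, series.pleasantness,
                                   atol=1e-9)
        np.testing.assert_allclose(back.weights, series.weights, atol=1e-9)
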