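"""Layer decomposition: envelope tracking, exact reconstruction, routing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soniclimate.errors import InvalidConfigError
from soniclimate.frontend import Cochleogram
from soniclimate.layers import (LayerSet, decompose, reconstruct,
                                slow_envelope, sliding_low_quantile,
                                _sliding_quantile_brute,
                                _sliding_quantile_fenwick)
from soniclimate.scenes import routing_fractions


def brute_envelope(x, win, q):
    """Independent oracle: clamped trailing-window percentile per cell."""
    out = np.empty_like(x)
    for t in range(x.shape[0]):
        lo = max(0, t - win + 1)
        out[t] = np.quantile(x[lo:t + 1], q, method="lower", axis=0)
    return np.minimum(out, x)


class TestSlowEnvelope:
    def test_constant_input_tracked_exactly(self):
        x = np.full((100, 3), -42.0)
        env = slow_envelope(x, frame_rate=20.0, tau=1.0)
        assert np.all(env == -42.0)

    def test_single_frame_spike_rejected(self):
        x = np.full((200, 2), -60.0)
        x[100] = -30.0
        env = slow_envelope(x, frame_rate=20.0, tau=2.0)
        assert np.all(env == -60.0)

    def test_step_tracked_no_earlier_than_percentile_lag(self):
        fr, tau, q = 20.0, 2.0, 0.1
        x = np.full((200, 1), -60.0)
        x[80:] = -40.0
        env = slow_envelope(x, fr, tau, q)
        lag = int((1 - q) * tau * fr)
        assert np.all(env[80:80 + lag - 1] < -40.0)
        assert np.all(env[80 + int(tau * fr):] == -40.0)

    def test_tau_below_frame_period_rejected(self):
        with pytest.raises(InvalidConfigError):
            slow_envelope(np.zeros((10, 1)), frame_rate=20.0, tau=0.01)

    def test_envelope_never_exceeds_input(self):
        rng = np.random.default_rng(11)
        x = rng.normal(-50, 8, size=(300, 4))
        env = slow_envelope(x, 20.0, 1.5)
        assert np.all(env <= x + 1e-12)

    @pytest.mark.parametrize("win", [3, 17, 100, 640, 1000])
    def test_matches_bruteforce_percentile_oracle(self, win):
        rng = np.random.default_rng(win)
        x = rng.normal(-55, 10, size=(1500, 3))
        env = slow_envelope(x, frame_rate=1.0, tau=float(win), percentile=0.1)
        assert np.array_equal(env, brute_envelope(x, win, 0.1))

    @pytest.mark.parametrize("win", [5, 64, 700])
    def test_fenwick_and_partition_paths_bit_equal(self, win):
        rng = np.random.default_rng(win + 1)
        x = rng.normal(-55, 10, size=(900, 4))
        a = _sliding_quantile_brute(x, win, 0.1)
        b = _sliding_quantile_fenwick(x, win, 0.1)
        assert np.array_equal(a, b)

    def test_idempotent_on_sparse_event_signal(self):
        # a background with sparse upward events: re-running the tracker
        # on its own output changes nothing
        x = np.full((400, 2), -58.0)
        for t0 in (50, 140, 260, 330):
            x[t0:t0 + 3] = -30.0
        env = slow_envelope(x, 20.0, 2.0)
        again = slow_envelope(env, 20.0, 2.0)
        assert np.array_equal(env, again)


def make_coch(levels, frame_rate=20.0):
    n_ch = levels.shape[1]
    cf = np.geomspace(100.0, 8000.0, n_ch)
    return Cochleogram(levels, frame_rate, cf)


class TestDecompose:
    def test_stationary_noise_all_in_hour_background(self):
        rng = np.random.default_rng(0)
        lv = np.full((4000, 4), -48.0) + rng.normal(0, 0.2, (4000, 4))
        layers = decompose(make_coch(lv), taus=(1.0, 10.0, 100.0))
        tail = slice(2500, None)  # after warm-up of the slowest tau
        assert np.all(layers.second_fg[tail] < 2.0)
        assert np.all(layers.minute_fg[tail] < 2.0)
        assert np.all(layers.hour_fg[tail] < 2.0)
        assert np.abs(layers.hour_bg[tail] - (-48.0)).max() < 2.0

    def test_short_bursts_land_in_second_foreground(self):
        lv = np.full((1200, 3), -70.0)
        for t0 in range(100, 1100, 40):  # 0.2 s bursts every 2 s at 20 fps
            lv[t0:t0 + 4, 1] = -35.0
        layers = decompose(make_coch(lv), taus=(1.0, 10.0, 100.0))
        burst = lv[:, 1] > -70.0
        assert np.all(layers.second_fg[burst, 1] > 30.0)
        assert np.all(layers.minute_fg[burst, 1] < 1e-9)

    def test_20s_bump_lands_in_minute_foreground(self):
        lv = np.full((3000, 2), -60.0)
        lv[1000:1080] += 20.0  # 4 s bump at 20 fps, between taus 1 and 10
        layers = decompose(make_coch(lv), taus=(1.0, 10.0, 100.0))
        bump = slice(1030, 1080)  # past the 1 s envelope lag
        assert layers.minute_fg[bump].mean() > 15.0

    def test_envelope_ordering(self, routing_scene):
        layers = routing_scene["layers"]
        s1, s2, s3 = (layers.slow_envelopes[t] for t in layers.taus)
        assert np.all(s1 >= s2 - 1e-12)
        assert np.all(s2 >= s3 - 1e-12)

    def test_short_recording_flagged_provisional(self):
        lv = np.full((50, 2), -40.0)
        layers = decompose(make_coch(lv), taus=(0.5, 1.0, 60.0))
        assert layers.provisional.all()

    def test_nonincreasing_taus_rejected(self):
        with pytest.raises(InvalidConfigError):
            decompose(make_coch(np.zeros((10, 2))), taus=(1.0, 1.0, 2.0))


class TestReconstruction:
    def test_roundtrip_exact(self, routing_scene):
        rec = reconstruct(routing_scene["layers"])
        err = np.abs(rec - routing_scene["coch"].levels).max()
        assert err < 1e-9

    def test_silence_reconstructs_to_floor(self):
        lv = np.full((100, 3), -100.0)
        layers = decompose(make_coch(lv), taus=(0.5, 1.0, 2.0))
        assert np.all(reconstruct(layers) == -100.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_reconstruction_and_nonnegativity_any_input(self, seed):
        rng = np.random.default_rng(seed)
        lv = np.clip(rng.normal(-60, 12, size=(150, 3)), -100.0, None)
        layers = decompose(make_coch(lv), taus=(0.5, 1.5, 4.0))
        assert np.abs(reconstruct(layers) - lv).max() < 1e-9
        for name in ("second_fg", "minute_fg", "hour_fg"):
            assert layers.layer(name).min() >= 0.0


class TestRouting:
    def test_events_route_to_expected_layers(self, routing_scene):
        layers = routing_scene["layers"]
        for i, spec in enumerate(routing_scene["schedule"]):
            baseline = routing_scene["baselines"].get(i)
            frac = routing_fractions(layers, spec, baseline)
            assert frac[spec.expected_layer] >= 0.8, (
                f"{spec.kind} routed {frac}")


class TestSerialization:
    def test_layerset_roundtrip(self, routing_scene, tmp_path):
        layers = routing_scene["layers"]
        layers.save(tmp_path / "ls")
        back = LayerSet.load(tmp_path / "ls")
        np.testing.assert_allclose(back.minute_fg, layers.minute_fg, atol=1e-5)
        assert back.taus == tuple(layers.taus)
        assert back.frame_rate == layers.frame_rate
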