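"""Shared fixtures: scaled-tau synthetic scenes and hand-built layer sets.

Scenes use time constants {1, 10, 100} s instead of {1 s, 1 min, 1 h} —
the decomposition is parametric in tau, so routing behavior transfers —
with event durations keeping the same relative geometry (sub-second calls,
passages a few fast-taus long, quasi-stationary events spanning most of a
slow tau, a constant background).
"""

import numpy as np
import pytest

from soniclimate.appraisal import appraise_series
from soniclimate.config import default_config
from soniclimate.frontend import FrontendParams, make_center_freqs
from soniclimate.layers import LayerSet, decompose
from soniclimate.scenes import EventSpec, gen_scene_cochleogram

SCALED_TAUS = (1.0, 10.0, 100.0)
SAMPLE_RATE = 48000.0


@pytest.fixture(scope="session")
def params20():
    return FrontendParams(frame_rate=20.0)


@pytest.fixture(scope="session")
def center_freqs(params20):
    return make_center_freqs(params20, SAMPLE_RATE)


def routing_schedule(duration=260.0):
    """One event per target layer, placed over a constant background."""
    return [
        EventSpec("background", 0.0, duration, (50.0, 8000.0), -55.0,
                  expected_layer="hour_bg", expected_quadrant="boring"),
        EventSpec("pulse_train", 30.0, 8.0, (3000.0, 8000.0), -30.0,
                  rate=1.0, rise_fall=0.12,
                  expected_layer="second_fg", expected_quadrant="calm"),
        EventSpec("passage", 60.0, 8.0, (100.0, 6000.0), -30.0,
                  rise_fall=1.5,
                  expected_layer="minute_fg", expected_quadrant="chaotic"),
        EventSpec("quasi_stationary", 120.0, 75.0, (100.0, 4000.0), -35.0,
                  rise_fall=4.0,
                  expected_layer="hour_fg", expected_quadrant="boring"),
    ]


@pytest.fixture(scope="session")
def routing_scene(params20):
    """Scene cochleogram, its decomposition, and per-event baselines."""
    duration = 260.0
    schedule = routing_schedule(duration)
    for spec in schedule:
        spec.validate(SCALED_TAUS)
    coch = gen_scene_cochleogram(schedule, duration, params20,
                                 SAMPLE_RATE, seed=1).cochleogram
    layers = decompose(coch, taus=SCALED_TAUS)
    baselines = {}
    for i, spec in enumerate(schedule):
        if spec.kind == "background":
            continue
        rest = [s for j, s in enumerate(schedule) if j != i]
        baselines[i] = gen_scene_cochleogram(
            rest, duration, params20, SAMPLE_RATE, seed=1
        ).cochleogram.levels
    return {"schedule": schedule, "coch": coch, "layers": layers,
            "baselines": baselines}


@pytest.fixture(scope="session")
def mixed_scene(params20):
    """Bird-chorus and car-passage segments for end-to-end appraisal."""
    taus = SCALED_TAUS
    schedule = [
        EventSpec("background", 0.0, 120.0, (50.0, 8000.0), -65.0),
        EventSpec("pulse_train", 20.0, 20.0, (3000.0, 8000.0), -35.0,
                  rate=2.0, rise_fall=0.12, expected_quadrant="calm"),
        EventSpec("passage", 80.0, 8.0, (100.0, 2300.0), -32.0,
                  rise_fall=3.0, expected_quadrant="chaotic"),
    ]
    coch = gen_scene_cochleogram(schedule, 120.0, params20,
                                 SAMPLE_RATE, seed=3).cochleogram
    layers = decompose(coch, taus=taus)
    series = appraise_series(layers, default_config(taus=taus))
    return {"schedule": schedule, "coch": coch, "layers": layers,
            "series": series,
            "bird_seconds": slice(21, 40), "car_seconds": slice(81, 88)}


@pytest.fixture()
def make_layerset(center_freqs):
    """Hand-built LayerSet factory for appraisal unit tests."""

    def _make(n_frames=200, frame_rate=20.0, floor=-100.0, **overrides):
        n_ch = center_freqs.shape[0]
        mats = {
            "second_fg": np.zeros((n_frames, n_ch)),
            "minute_fg": np.zeros((n_frames, n_ch)),
            "hour_fg": np.zeros((n_frames, n_ch)),
            "hour_bg": np.full((n_frames, n_ch), floor),
        }
        mats.update(overrides)
        return LayerSet(
            **mats, slow_envelopes={}, taus=SCALED_TAUS, percentile=0.1,
            frame_rate=frame_rate, center_freqs=center_freqs,
            floor_db=floor, calibration_offset=97.0,
        )

    return _make
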