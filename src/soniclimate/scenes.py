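"""Seeded synthetic acoustic scenes with ground-truth labels.

Generates schematic stand-ins for the source taxonomy the appraisal
pipeline targets — sub-second high-frequency pulse trains (bird-like
calls), sub-second vocal-band events, 5-30 s broadband passages (cars),
minute-scale quasi-stationary sounds (machinery, rain) and a constant
broadband background — either as audio waveforms or directly as
cochleogram-domain energy patches (synthesizing hours of audio to test an
hour-scale envelope is wasteful).  Every event carries the layer and
circumplex quadrant it is expected to land in, so decomposition routing
and end-to-end appraisal can be scored against ground truth.

All realizations are bit-identical for a given (schedule, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidConfigError, InvalidInputError
from .frontend import Cochleogram, FrontendParams, make_center_freqs
from .layers import LayerSet, DEFAULT_TAUS

__all__ = [
    "EventSpec",
    "SceneBundle",
    "gen_event",
    "gen_scene",
    "gen_scene_cochleogram",
    "event_support",
    "routing_fractions",
    "expected_layer_for_duration",
    "bird_chorus_schedule",
    "car_passage_schedule",
    "save_schedule",
    "load_schedule",
]

log = logging.getLogger(__name__)

KINDS = ("pulse_train", "passage", "quasi_stationary", "background", "ramp")


def expected_layer_for_duration(duration: float, constant: bool = False,
                                taus=DEFAULT_TAUS) -> str:
    """Layer an event of a given duration should route to."""
    if constant:
        return "hour_bg"
    if duration < taus[0]:
        return "second_fg"
    if duration < taus[1]:
        return "minute_fg"
    if duration < taus[2]:
        return "hour_fg"
    return "hour_bg"


@dataclass
class EventSpec:
    """One scheduled sound event and its ground-truth labels.

    ``peak_level`` is the RMS level in dB re full scale at the envelope
    peak.  ``rate`` applies to pulse trains (pulses per second); pulses are
    Hann-shaped with total width ``2 * rise_fall``.
    """

    kind: str
    t_start: float
    duration: float
    band: tuple  # (f_lo, f_hi) Hz
    peak_level: float
    rate: float = 2.0
    rise_fall: float = 0.1
    expected_layer: str | None = None
    expected_quadrant: str | None = None

    def validate(self, taus=DEFAULT_TAUS) -> "EventSpec":
        if self.kind not in KINDS:
            raise InvalidConfigError(f"unknown event kind {self.kind!r}")
        if self.duration <= 0:
            raise InvalidConfigError("event duration must be > 0")
        if not self.band[0] < self.band[1]:
            raise InvalidConfigError("band lower edge must be < upper edge")
        if self.expected_layer is not None:
            per_event = (2 * self.rise_fall if self.kind == "pulse_train"
                         else self.duration)
            implied = expected_layer_for_duration(
                per_event, constant=self.kind == "background", taus=taus)
            if implied != self.expected_layer:
                raise InvalidConfigError(
                    f"expected_layer {self.expected_layer!r} inconsistent with "
                    f"event time scale {per_event:g} s (implies {implied!r})"
                )
        return self


@dataclass
class SceneBundle:
    """A realized scene plus its generating schedule (the ground truth)."""

    sample_rate: float
    events: list
    seed: int
    samples: np.ndarray | None = None
    cochleogram: Cochleogram | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Envelopes (amplitude domain, peak 1)

def _envelope(spec: EventSpec, t: np.ndarray) -> np.ndarray:
    """Amplitude envelope of an event on a relative time axis (seconds)."""
    d = spec.duration
    if spec.kind == "pulse_train":
        env = np.zeros_like(t)
        width = 2.0 * spec.rise_fall
        period = 1.0 / spec.rate
        k = 0
        while True:
            center = k * period + width / 2.0
            if center + width / 2.0 > d:
                break
            phase = (t - center) / width  # in [-0.5, 0.5] inside the pulse
            inside = np.abs(phase) <= 0.5
            env[inside] = np.maximum(env[inside],
                                     np.cos(np.pi * phase[inside]) ** 2)
            k += 1
        return env
    if spec.kind in ("passage", "quasi_stationary"):
        rf = min(spec.rise_fall, d / 2.0)
        env = np.ones_like(t)
        if rf > 0:
            rising = t < rf
            falling = t > d - rf
            env[rising] = np.sin(0.5 * np.pi * t[rising] / rf) ** 2
            env[falling] = np.sin(0.5 * np.pi * (d - t[falling]) / rf) ** 2
        env[(t < 0) | (t > d)] = 0.0
        return env
    if spec.kind == "background":
        return np.ones_like(t)
    if spec.kind == "ramp":
        return np.clip(t / d, 0.0, 1.0)
    raise InvalidConfigError(f"unknown event kind {spec.kind!r}")


def _band_noise(n: int, sample_rate: float, band, rng) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` by spectral masking."""
    f_lo, f_hi = band
    nyquist = sample_rate / 2.0
    if f_lo >= nyquist:
        raise InvalidConfigError(
            f"band [{f_lo}, {f_hi}] Hz lies outside Nyquist ({nyquist:.0f} Hz)"
        )
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    spec[(freqs < f_lo) | (freqs >= min(f_hi, nyquist))] = 0.0
    y = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(y ** 2))
    if rms == 0:
        raise InvalidConfigError("band too narrow: no spectral energy left")
    return y / rms


def gen_event(spec: EventSpec, sample_rate: float, seed: int = 0) -> np.ndarray:
    """Realize one event as samples of length ``round(duration * fs)``."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * sample_rate))
    noise = _band_noise(n, sample_rate, spec.band, rng)
    t = np.arange(n) / sample_rate
    env = _envelope(spec, t)
    return 10.0 ** (spec.peak_level / 20.0) * env * noise


def gen_scene(schedule, duration: float, sample_rate: float,
              seed: int = 0) -> SceneBundle:
    """Mix a schedule of events into one waveform, with ground truth.

    Event seeds are spawned deterministically from ``seed`` by position in
    the schedule; overlapping events are summed (a clipping warning is
    logged if the mix leaves full scale).
    """
    n = int(round(duration * sample_rate))
    mix = np.zeros(n)
    children = np.random.SeedSequence(seed).spawn(max(len(schedule), 1))
    for spec, child in zip(schedule, children):
        spec.validate()
        if spec.t_start < 0 or spec.t_start + spec.duration > duration + 1e-9:
            raise InvalidInputError(
                f"event at t={spec.t_start} s does not fit in {duration} s"
            )
        ev = gen_event(spec, sample_rate, seed=child.generate_state(1)[0] % (2 ** 31))
        start = int(round(spec.t_start * sample_rate))
        stop = min(start + ev.shape[0], n)
        mix[start:stop] += ev[: stop - start]
    peak = np.abs(mix).max() if n else 0.0
    if peak > 1.0:
        log.warning("scene mix peaks at %.2f x full scale", peak)
    return SceneBundle(sample_rate=sample_rate, events=list(schedule),
                       seed=seed, samples=mix,
                       meta={"duration": duration})


def gen_scene_cochleogram(schedule, duration: float,
                          params: FrontendParams | None = None,
                          sample_rate: float = 48000.0,
                          seed: int = 0,
                          level_jitter_db: float = 0.0) -> SceneBundle:
    """Realize a schedule directly as cochleogram-domain energy patches.

    Each event adds ``10**(peak_level/10) * envelope(t)^2`` of energy to
    every channel whose center frequency lies in its band; energies of
    overlapping events sum.  ``level_jitter_db`` optionally roughens each
    active cell with seeded Gaussian level noise to emulate the frame-to-
    frame variability of filtered noise.
    """
    if params is None:
        params = FrontendParams()
    center_freqs = make_center_freqs(params, sample_rate)
    n_frames = int(np.ceil(duration * params.frame_rate))
    floor_energy = 10.0 ** (params.floor_db / 10.0)
    energy = np.full((n_frames, center_freqs.shape[0]), floor_energy)
    rng = np.random.default_rng(seed)
    for spec in schedule:
        spec.validate()
        if spec.t_start < 0 or spec.t_start + spec.duration > duration + 1e-9:
            raise InvalidInputError(
                f"event at t={spec.t_start} s does not fit in {duration} s"
            )
        frames, mask = event_support(spec, params.frame_rate, center_freqs,
                                     n_frames)
        if not mask.any():
            raise InvalidConfigError(
                f"band {spec.band} matches no analysis channel"
            )
        t_rel = (np.arange(frames.start, frames.stop) / params.frame_rate
                 - spec.t_start)
        env2 = _envelope(spec, t_rel) ** 2
        patch = 10.0 ** (spec.peak_level / 10.0) * env2[:, None]
        if level_jitter_db > 0:
            jitter = rng.normal(0.0, level_jitter_db,
                                size=(t_rel.shape[0], int(mask.sum())))
            patch = patch * 10.0 ** (jitter / 10.0)
        # energy[frames] is a basic-slice view, so this adds in place
        energy[frames, :][:, mask] += patch
    levels = 10.0 * np.log10(np.maximum(energy, floor_energy))
    coch = Cochleogram(
        levels=levels, frame_rate=params.frame_rate, center_freqs=center_freqs,
        calibration_offset=params.calibration_offset, floor_db=params.floor_db,
        meta={"synthetic": True, "seed": int(seed)},
    ).validate()
    return SceneBundle(sample_rate=sample_rate, events=list(schedule),
                       seed=seed, cochleogram=coch,
                       meta={"duration": duration})


def event_support(spec: EventSpec, frame_rate: float, center_freqs,
                  n_frames: int | None = None):
    """Time-frequency support of an event: (frame slice, channel mask)."""
    start = int(np.floor(spec.t_start * frame_rate))
    stop = int(np.ceil((spec.t_start + spec.duration) * frame_rate))
    if n_frames is not None:
        stop = min(stop, n_frames)
    cf = np.asarray(center_freqs, dtype=float)
    mask = (cf >= spec.band[0]) & (cf < spec.band[1])
    return slice(max(start, 0), stop), mask


def routing_fractions(layers: LayerSet, spec: EventSpec,
                      baseline_levels: np.ndarray | None = None) -> dict:
    """Fraction of an event's above-baseline level mass per layer.

    Mass is measured in dB-above-baseline units over the event's
    time-frequency support.  ``baseline_levels`` is the level matrix the
    scene would have had without this event (e.g. the same schedule
    re-rendered with the event removed); it defaults to the level floor,
    which is only appropriate for events placed over silence.  The layers
    partition the level exactly, so the four fractions sum to 1.
    """
    frames, mask = event_support(spec, layers.frame_rate, layers.center_freqs,
                                 layers.n_frames)
    if baseline_levels is None:
        ref = layers.floor_db
    else:
        ref = np.asarray(baseline_levels, dtype=float)[frames][:, mask]
    total = 0.0
    per_layer = {}
    for name in ("second_fg", "minute_fg", "hour_fg"):
        m = float(layers.layer(name)[frames][:, mask].sum())
        per_layer[name] = m
        total += m
    bg = float(np.clip(layers.hour_bg[frames][:, mask] - ref, 0.0, None).sum())
    per_layer["hour_bg"] = bg
    total += bg
    if total <= 0:
        raise InvalidInputError("event support holds no above-baseline energy")
    return {k: v / total for k, v in per_layer.items()}


# ---------------------------------------------------------------------------
# Ready-made schedules

def bird_chorus_schedule(t_start: float, duration: float,
                         peak_level: float = -35.0, rate: float = 3.0):
    """High-band pulse trains: bird-like calls expected to appraise calm."""
    return [EventSpec("pulse_train", t_start, duration, (3000.0, 8000.0),
                      peak_level, rate=rate, rise_fall=0.1,
                      expected_layer="second_fg", expected_quadrant="calm")]


def car_passage_schedule(t_starts, passage_duration: float = 15.0,
                         peak_level: float = -30.0):
    """Broadband passages: car-like events expected to appraise chaotic."""
    return [EventSpec("passage", t0, passage_duration, (50.0, 8000.0),
                      peak_level, rise_fall=passage_duration / 4.0,
                      expected_layer="minute_fg", expected_quadrant="chaotic")
            for t0 in t_starts]


# ---------------------------------------------------------------------------
# Schedule I/O

def save_schedule(schedule, path) -> None:
    payload = [asdict(s) for s in schedule]
    for row in payload:
        row["band"] = list(row["band"])
    text = json.dumps(payload, indent=1)
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def load_schedule(path):
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            payload = json.load(fh)
    out = []
    for row in payload:
        row = dict(row)
        row["band"] = tuple(row["band"])
        out.append(EventSpec(**row))
    return out
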