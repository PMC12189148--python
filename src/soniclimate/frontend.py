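"""Cochleogram-style time-frequency front end.

Converts PCM audio into a tonotopic (ERB- or log-spaced) matrix of band
energy levels in dB — the common currency of every later stage.  The band
grouping is gammatone-shaped in frequency and power-normalized per FFT bin,
so the sum of all channel energies equals the total signal power and a pure
tone always peaks in the channel whose center frequency is nearest to it.

Levels are stored in dB relative to digital full scale and floored (default
-100 dB).  A user-supplied ``calibration_offset`` maps them to approximate
dB SPL when broadband dB(A) levels are computed; the default offset places a
full-scale sine near 94 dB(A).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "FrontendParams",
    "Cochleogram",
    "compute_cochleogram",
    "a_weighting",
    "broadband_level_dba",
    "broadband_series",
    "erb_number",
    "erb_number_to_hz",
    "erb_bandwidth",
]

log = logging.getLogger(__name__)

#: Default calibration so that a full-scale 1 kHz sine reads ~94 dB(A)
#: (its mean square is 1/2, i.e. -3.01 dBFS; -3.01 + 97.0 = 93.99).
DEFAULT_CALIBRATION_DB = 97.0


# ---------------------------------------------------------------------------
# ERB scale (Glasberg & Moore)

def erb_number(freq_hz):
    """Map frequency in Hz to the ERB-number (Cam) scale."""
    f = np.asarray(freq_hz, dtype=float)
    return 21.4 * np.log10(4.37 * f / 1000.0 + 1.0)


def erb_number_to_hz(erb):
    """Inverse of :func:`erb_number`."""
    e = np.asarray(erb, dtype=float)
    return (10.0 ** (e / 21.4) - 1.0) * 1000.0 / 4.37


def erb_bandwidth(freq_hz):
    """Equivalent rectangular bandwidth (Hz) at ``freq_hz``."""
    f = np.asarray(freq_hz, dtype=float)
    return 24.7 * (4.37 * f / 1000.0 + 1.0)


# ---------------------------------------------------------------------------
# Parameters and container

@dataclass(frozen=True)
class FrontendParams:
    """Configuration of the time-frequency front end.

    Attributes
    ----------
    n_channels:
        Number of tonotopic channels (>= 16).
    lower_edge, upper_edge:
        Frequency span in Hz.  ``upper_edge`` is clamped at analysis time to
        ``0.45 * sample_rate``.
    frame_rate:
        Output frames per second (>= 10).
    spacing:
        ``"erb"`` (equal spacing on the ERB-number scale) or ``"log"``.
    floor_db:
        Level floor in dB re full scale; silence maps exactly here.
    calibration_offset:
        dB added when converting to approximate dB SPL / dB(A).
    """

    n_channels: int = 64
    lower_edge: float = 50.0
    upper_edge: float = 23000.0
    frame_rate: float = 50.0
    spacing: str = "erb"
    floor_db: float = -100.0
    calibration_offset: float = DEFAULT_CALIBRATION_DB

    def __post_init__(self):
        if not self.lower_edge < self.upper_edge:
            raise InvalidConfigError("lower_edge must be < upper_edge")
        if self.frame_rate < 10:
            raise InvalidConfigError("frame_rate must be >= 10 frames/s")
        if self.n_channels < 16:
            raise InvalidConfigError("n_channels must be >= 16")
        if self.spacing not in ("erb", "log"):
            raise InvalidConfigError(f"unknown spacing {self.spacing!r}")


@dataclass
class Cochleogram:
    """Time x frequency matrix of band levels in dB.

    ``levels`` has shape ``(n_frames, n_channels)``; ``center_freqs`` is
    strictly increasing.  Levels are dB re full scale, floored at
    ``floor_db``; ``calibration_offset`` maps them to approximate dB SPL.
    """

    levels: np.ndarray
    frame_rate: float
    center_freqs: np.ndarray
    calibration_offset: float = DEFAULT_CALIBRATION_DB
    floor_db: float = -100.0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.levels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.levels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def validate(self) -> "Cochleogram":
        lv = np.asarray(self.levels, dtype=float)
        cf = np.asarray(self.center_freqs, dtype=float)
        if lv.ndim != 2 or lv.shape[1] != cf.shape[0]:
            raise InvalidInputError("levels shape does not match center_freqs")
        if not np.all(np.diff(cf) > 0):
            raise InvalidInputError("center_freqs must be strictly increasing")
        if not np.all(np.isfinite(lv)):
            raise InvalidInputError("levels contain non-finite values")
        if lv.size and lv.min() < self.floor_db - 1e-9:
            raise InvalidInputError("levels below the configured floor")
        return self

    # -- serialization: CSV matrix + JSON header -------------------------
    def save(self, path_stem: str) -> None:
        """Write ``<stem>.csv`` (levels) and ``<stem>.json`` (metadata)."""
        np.savetxt(str(path_stem) + ".csv", self.levels, delimiter=",", fmt="%.6f")
        header = {
            "frame_rate": self.frame_rate,
            "center_freqs": list(map(float, self.center_freqs)),
            "calibration_offset": self.calibration_offset,
            "floor_db": self.floor_db,
            "meta": self.meta,
        }
        with open(str(path_stem) + ".json", "w") as fh:
            json.dump(header, fh, indent=1)

    @classmethod
    def load(cls, path_stem: str) -> "Cochleogram":
        with open(str(path_stem) + ".json") as fh:
            header = json.load(fh)
        levels = np.atleast_2d(np.loadtxt(str(path_stem) + ".csv", delimiter=","))
        return cls(
            levels=levels,
            frame_rate=header["frame_rate"],
            center_freqs=np.asarray(header["center_freqs"], dtype=float),
            calibration_offset=header["calibration_offset"],
            floor_db=header["floor_db"],
            meta=header.get("meta", {}),
        ).validate()


# ---------------------------------------------------------------------------
# Filterbank construction

def make_center_freqs(params: FrontendParams, sample_rate: float) -> np.ndarray:
    """Channel center frequencies for ``params`` at a given sample rate."""
    upper = min(params.upper_edge, 23000.0, 0.45 * sample_rate)
    if upper < params.upper_edge:
        log.warning(
            "upper edge clamped from %.0f to %.0f Hz (sample rate %.0f)",
            params.upper_edge, upper, sample_rate,
        )
    if upper <= params.lower_edge:
        raise InvalidConfigError("clamped upper edge fell below lower_edge")
    if params.spacing == "erb":
        grid = np.linspace(erb_number(params.lower_edge), erb_number(upper),
                           params.n_channels)
        cf = erb_number_to_hz(grid)
    else:
        cf = np.exp(np.linspace(math.log(params.lower_edge), math.log(upper),
                                params.n_channels))
    # scale round-trips can overshoot the edges by float round-off
    return np.clip(cf, params.lower_edge, upper)


def _filter_weights(center_freqs: np.ndarray, fft_freqs: np.ndarray) -> np.ndarray:
    """Squared, per-bin power-normalized channel gains, shape (C, n_bins).

    Each channel's amplitude response is gammatone-shaped,
    ``[1 + ((f - fc)/(b/2))^2]^-2`` with ``b`` the ERB at fc.  The squared
    gains are then normalized so each FFT bin's total weight across channels
    is 1: the channel-energy sum equals the total (one-sided) signal power,
    and a tone at any channel's center frequency peaks in that channel.
    """
    fc = center_freqs[:, None]
    half_b = erb_bandwidth(center_freqs)[:, None] / 2.0
    w2 = (1.0 + ((fft_freqs[None, :] - fc) / half_b) ** 2) ** -4.0
    norm = w2.sum(axis=0)
    return w2 / np.maximum(norm, 1e-30)


def compute_cochleogram(samples, sample_rate: float,
                        params: FrontendParams | None = None) -> Cochleogram:
    """Analyze PCM samples into a cochleogram.

    Multichannel input is averaged to mono.  Frames are taken at
    ``1/frame_rate`` hops with a Hann window of four hops (75% overlap);
    the last frames are zero-padded.  Identical input gives bit-identical
    output.
    """
    if params is None:
        params = FrontendParams()
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty sample array")
    if sample_rate < 8000:
        raise InvalidInputError("sample_rate must be >= 8000 Hz")
    if x.ndim == 2:
        log.info("averaging %d channels to mono", x.shape[1])
        x = x.mean(axis=1)
    elif x.ndim != 1:
        raise InvalidInputError("samples must be 1-D or 2-D")

    hop = sample_rate / params.frame_rate
    n_frames = int(math.ceil(x.shape[0] / hop))
    nperseg = 2 * int(round(2 * hop))  # 4 hops, even
    window = np.hanning(nperseg)

    starts = np.round(np.arange(n_frames) * hop).astype(int)
    pad = starts[-1] + nperseg - x.shape[0]
    if pad > 0:
        x = np.concatenate([x, np.zeros(pad)])
    # gather explicitly: hops may be a non-integer number of samples
    frames = x[starts[:, None] + np.arange(nperseg)[None, :]]

    spec = np.fft.rfft(frames * window, axis=1)
    power = np.abs(spec) ** 2
    # one-sided scaling: sum over bins == window-weighted mean square
    scale = np.full(power.shape[1], 2.0)
    scale[0] = 1.0
    if nperseg % 2 == 0:
        scale[-1] = 1.0
    power *= scale / (nperseg * np.sum(window ** 2))

    center_freqs = make_center_freqs(params, sample_rate)
    fft_freqs = np.fft.rfftfreq(nperseg, 1.0 / sample_rate)
    weights = _filter_weights(center_freqs, fft_freqs)

    energies = power @ weights.T
    floor_energy = 10.0 ** (params.floor_db / 10.0)
    levels = 10.0 * np.log10(np.maximum(energies, floor_energy))

    return Cochleogram(
        levels=levels,
        frame_rate=params.frame_rate,
        center_freqs=center_freqs,
        calibration_offset=params.calibration_offset,
        floor_db=params.floor_db,
        meta={"sample_rate": float(sample_rate), "n_samples": int(len(samples))},
    ).validate()


# ---------------------------------------------------------------------------
# A-weighting and broadband levels

_F1, _F2, _F3, _F4 = 20.598997, 107.65265, 737.86223, 12194.217


def _ra(f):
    f2 = f * f
    return (_F4 ** 2 * f2 * f2) / (
        (f2 + _F1 ** 2)
        * np.sqrt((f2 + _F2 ** 2) * (f2 + _F3 ** 2))
        * (f2 + _F4 ** 2)
    )


_A1000 = 20.0 * math.log10(_ra(np.array(1000.0)))


def a_weighting(freq_hz):
    """Standard A-weighting gain in dB (exactly 0 at 1 kHz).

    Implements the IEC 61672 pole-zero magnitude response, referenced to
    1 kHz.  Scalar or array input; raises for non-positive frequencies.
    """
    f = np.asarray(freq_hz, dtype=float)
    if np.any(f <= 0):
        raise InvalidInputError("frequency must be positive")
    out = 20.0 * np.log10(_ra(f)) - _A1000
    return float(out) if np.isscalar(freq_hz) or out.ndim == 0 else out


def _broadband_dba_from_levels(levels, center_freqs, floor_db, calibration_offset):
    """dB(A) of one or more frames of band levels.

    Channels at (or below) the floor are silence sentinels and contribute
    no energy; an all-floor frame returns ``floor_db + calibration_offset``.
    """
    lv = np.atleast_2d(np.asarray(levels, dtype=float))
    aw = a_weighting(np.asarray(center_freqs, dtype=float))
    energy = 10.0 ** ((lv + aw[None, :]) / 10.0)
    energy[lv <= floor_db + 1e-12] = 0.0
    total = energy.sum(axis=1)
    out = np.full(total.shape, floor_db + calibration_offset)
    nz = total > 0
    out[nz] = 10.0 * np.log10(total[nz]) + calibration_offset
    return out


def broadband_level_dba(coch: Cochleogram, frame: int) -> float:
    """A-weighted broadband level (approximate dB(A)) of one frame."""
    if not -coch.n_frames <= frame < coch.n_frames:
        raise IndexError(f"frame {frame} out of range (n={coch.n_frames})")
    return float(
        _broadband_dba_from_levels(
            coch.levels[frame], coch.center_freqs, coch.floor_db,
            coch.calibration_offset,
        )[0]
    )


def broadband_series(coch: Cochleogram) -> np.ndarray:
    """A-weighted broadband level of every frame, shape (n_frames,)."""
    return _broadband_dba_from_levels(
        coch.levels, coch.center_freqs, coch.floor_db, coch.calibration_offset
    )
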