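"""Per-second circumplex appraisal from perceptual layers.

Every second, each configuration row contributes a weight in [0, 1]
(linear within its value range) pulling the appraisal point along its
quadrant's diagonal of the pleasantness x eventfulness plane:

    calm    -> (+1, -1)/sqrt(2)      lively  -> (+1, +1)/sqrt(2)
    chaotic -> (-1, +1)/sqrt(2)      boring  -> (-1, -1)/sqrt(2)
    center  -> (0, 0)

The point is the weighted vector sum ``sum(w_i * u_i) / max(1, sum(w_i))``,
radially clipped to the unit disk.  "Center" rows pull toward the origin:
their zero vector still enters the normalizing denominator, damping
extremity.  A single saturated row reaches the rim of its diagonal; silence
maps to the origin.

Row values are pooled over a look-back window of ``scope`` seconds: the
per-frame maximum across the row's band channels, then the 90th percentile
over the frames of the window where the band is active (audibility > 0),
so brief vocal events influence several consecutive appraisals.  Hour
background rows use the A-weighted broadband level (dB(A)) instead of band
audibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AppraisalConfig, ConfigRow, default_config
from .errors import InvalidConfigError, InvalidInputError
from .frontend import _broadband_dba_from_levels
from .layers import LayerSet

__all__ = [
    "QUADRANT_VECTORS",
    "AppraisalFrame",
    "AppraisalSeries",
    "band_audibility",
    "contribution_weight",
    "appraise_second",
    "appraise_series",
    "n_seconds_for_duration",
]

_INV_SQRT2 = 1.0 / math.sqrt(2.0)

QUADRANT_VECTORS = {
    "calm": (+_INV_SQRT2, -_INV_SQRT2),
    "lively": (+_INV_SQRT2, +_INV_SQRT2),
    "chaotic": (-_INV_SQRT2, +_INV_SQRT2),
    "boring": (-_INV_SQRT2, -_INV_SQRT2),
    "center": (0.0, 0.0),
}

SCOPE_POOL_PERCENTILE = 90.0


# ---------------------------------------------------------------------------
# Row values

def _band_channel_mask(center_freqs: np.ndarray, band) -> np.ndarray:
    f_lo, f_hi = band
    cf = np.asarray(center_freqs, dtype=float)
    mask = (cf >= f_lo) & (cf < f_hi)
    if f_hi >= cf[-1]:  # make the topmost channel reachable
        mask |= cf == cf[-1]
        mask &= cf >= f_lo
    if not mask.any():
        raise InvalidConfigError(
            f"band [{f_lo}, {f_hi}) Hz matches no analysis channel"
        )
    return mask


def _second_window(t: int, scope: float, frame_rate: float,
                   n_frames: int) -> slice:
    """Frames of the scope window ending at (and including) second ``t``."""
    end = min(int(round((t + 1) * frame_rate)), n_frames)
    start = max(0, int(round((t + 1 - scope) * frame_rate)))
    if end <= start:
        raise InvalidInputError(f"second {t} is outside the recording")
    return slice(start, end)


def band_audibility(layer_matrix: np.ndarray, center_freqs: np.ndarray,
                    band, t: int, scope: float = 1.0,
                    frame_rate: float = 50.0) -> float:
    """Pooled audibility (dB) of one layer in one band at second ``t``.

    Per-frame maximum across the band's channels, then the 90th percentile
    across the active frames (band maximum > 0) of the ``scope``-second
    window ending at ``t`` (truncated at the recording start).  Returns 0
    when the band is silent throughout the window.
    """
    if t < 0:
        raise InvalidInputError("second index must be >= 0")
    mat = np.asarray(layer_matrix, dtype=float)
    mask = _band_channel_mask(center_freqs, band)
    win = _second_window(t, scope, frame_rate, mat.shape[0])
    frame_max = mat[win][:, mask].max(axis=1)
    active = frame_max[frame_max > 0]
    if active.size == 0:
        return 0.0
    return float(np.percentile(active, SCOPE_POOL_PERCENTILE))


def contribution_weight(value: float, value_range) -> float:
    """Linear 0..1 weight of a row value within its range (clipped)."""
    v_min, v_max = value_range
    if not v_min < v_max:
        raise InvalidConfigError("value range min must be < max")
    return float(np.clip((value - v_min) / (v_max - v_min), 0.0, 1.0))


def _row_frame_series(layers: LayerSet, row: ConfigRow) -> np.ndarray:
    """Per-frame value series a row is pooled from."""
    mat = layers.layer(row.layer)
    if row.unit == "level_dba":
        return _broadband_dba_from_levels(
            mat, layers.center_freqs, layers.floor_db, layers.calibration_offset
        )
    mask = _band_channel_mask(layers.center_freqs, row.band)
    return mat[:, mask].max(axis=1)


def _pool(series: np.ndarray, row: ConfigRow, t: int, frame_rate: float) -> float:
    win = _second_window(t, row.scope, frame_rate, series.shape[0])
    vals = series[win]
    if row.unit == "audibility_db":
        vals = vals[vals > 0]
        if vals.size == 0:
            return 0.0
    return float(np.percentile(vals, SCOPE_POOL_PERCENTILE))


# ---------------------------------------------------------------------------
# Results

@dataclass
class AppraisalFrame:
    """One second's appraisal point in the circumplex unit disk."""

    t: int
    pleasantness: float
    eventfulness: float
    contributions: np.ndarray  # per-row weight, order of config.rows

    @property
    def magnitude(self) -> float:
        return math.hypot(self.pleasantness, self.eventfulness)


@dataclass
class AppraisalSeries:
    """Time-ordered appraisals, one per full second of input."""

    t: np.ndarray
    pleasantness: np.ndarray
    eventfulness: np.ndarray
    weights: np.ndarray  # (n_seconds, n_rows)
    config: AppraisalConfig
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.t.shape[0]

    def __getitem__(self, i: int) -> AppraisalFrame:
        return AppraisalFrame(int(self.t[i]), float(self.pleasantness[i]),
                              float(self.eventfulness[i]), self.weights[i])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t": self.t,
            "pleasantness": self.pleasantness,
            "eventfulness": self.eventfulness,
        })
        for i, row in enumerate(self.config.rows):
            df[f"w_{row.layer}_{row.quadrant}_{int(row.band[0])}_{int(row.band[1])}"] \
                = self.weights[:, i]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: AppraisalConfig | None = None) -> "AppraisalSeries":
        df = pd.read_csv(path)
        wcols = [c for c in df.columns if c.startswith("w_")]
        return cls(
            t=df["t"].to_numpy(dtype=int),
            pleasantness=df["pleasantness"].to_numpy(dtype=float),
            eventfulness=df["eventfulness"].to_numpy(dtype=float),
            weights=df[wcols].to_numpy(dtype=float) if wcols
            else np.zeros((len(df), 0)),
            config=config if config is not None else default_config(),
        )


# ---------------------------------------------------------------------------
# Appraisal proper

def _combine(weights: np.ndarray, vectors: np.ndarray):
    """Weighted vector sum, normalized and radially clipped to the disk."""
    total = weights.sum()
    p, e = weights @ vectors / max(1.0, total)
    r = math.hypot(p, e)
    if r > 1.0:
        p, e = p / r, e / r
    return p, e


def appraise_second(layers: LayerSet, config: AppraisalConfig | None = None,
                    t: int = 0) -> AppraisalFrame:
    """Appraise one second of a decomposed recording."""
    if config is None:
        config = default_config()
    config.validate()
    n_seconds = int(layers.n_frames // layers.frame_rate)
    if not 0 <= t < max(n_seconds, 1):
        raise InvalidInputError(f"second {t} outside recording ({n_seconds} s)")
    weights = np.empty(len(config.rows))
    for i, row in enumerate(config.rows):
        series = _row_frame_series(layers, row)
        value = _pool(series, row, t, layers.frame_rate)
        weights[i] = contribution_weight(value, row.value_range)
    vectors = np.array([QUADRANT_VECTORS[r.quadrant] for r in config.rows])
    p, e = _combine(weights, vectors)
    return AppraisalFrame(t=t, pleasantness=p, eventfulness=e,
                          contributions=weights)


def appraise_series(layers: LayerSet,
                    config: AppraisalConfig | None = None) -> AppraisalSeries:
    """Appraise every full second of a decomposed recording."""
    if config is None:
        config = default_config()
    config.validate()
    n_seconds = int(layers.n_frames // layers.frame_rate)
    rows = config.rows
    vectors = np.array([QUADRANT_VECTORS[r.quadrant] for r in rows])
    series = [_row_frame_series(layers, row) for row in rows]

    weights = np.zeros((n_seconds, len(rows)))
    p = np.zeros(n_seconds)
    e = np.zeros(n_seconds)
    for t in range(n_seconds):
        for i, row in enumerate(rows):
            weights[t, i] = contribution_weight(
                _pool(series[i], row, t, layers.frame_rate), row.value_range
            )
        p[t], e[t] = _combine(weights[t], vectors)
    return AppraisalSeries(
        t=np.arange(n_seconds), pleasantness=p, eventfulness=e,
        weights=weights, config=config, meta=dict(layers.meta),
    )


def n_seconds_for_duration(duration_s: float, frame_rate: float = 50.0) -> int:
    """Appraisal frames produced for a recording of ``duration_s`` seconds.

    Analytic counterpart of running the pipeline: the front end emits
    ``ceil(duration * frame_rate)`` frames and the appraisal one frame per
    full second, i.e. ``floor(n_frames / frame_rate)``.
    """
    n_frames = math.ceil(duration_s * frame_rate)
    return int(n_frames // frame_rate)
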