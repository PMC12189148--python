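"""Perceptual-layer decomposition by cascaded slow-envelope subtraction.

The cochleogram is split into four additive layers separated by three time
constants (defaults 1 s, 1 min, 1 h), implementing the old-plus-new
heuristic: each stage tracks a slow background estimate (a causal running
low percentile over a window of one time constant, clamped to never exceed
its input) and the residual above it is the faster foreground.

By construction the three foregrounds are non-negative audibilities in dB
above the next slower level, the slow envelopes are ordered
``S_fast >= S_slow``, and the four layers sum back to the input exactly.

The running percentile is the k-th order statistic of the trailing window
with ``k = floor(p * (m - 1))`` (``numpy`` quantile method ``"lower"``).
Two implementations produce bit-identical output: a vectorized brute-force
partition for short windows and a Fenwick-tree order-statistic sweep,
O(log n) per frame, for long ones (an hour-long window must not cost
O(window) per frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError, InvalidInputError
from .frontend import Cochleogram

__all__ = [
    "LayerSet",
    "slow_envelope",
    "decompose",
    "reconstruct",
    "sliding_low_quantile",
    "DEFAULT_TAUS",
]

DEFAULT_TAUS = (1.0, 60.0, 3600.0)
DEFAULT_PERCENTILE = 0.10

LAYER_NAMES = ("second_fg", "minute_fg", "hour_fg", "hour_bg")

#: window length (frames) above which the Fenwick-tree path is used
_BRUTE_MAX_WINDOW = 512


# ---------------------------------------------------------------------------
# Sliding low-quantile kernels

def _sliding_quantile_brute(x: np.ndarray, win: int, q: float) -> np.ndarray:
    """Reference path: trailing-window quantile via partition, per frame."""
    n = x.shape[0]
    out = np.empty_like(x)
    warm = min(win - 1, n)
    for t in range(warm):  # growing warm-up window
        k = int(np.floor(q * t))
        out[t] = np.partition(x[: t + 1], k, axis=0)[k]
    if n >= win:
        k = int(np.floor(q * (win - 1)))
        sw = np.lib.stride_tricks.sliding_window_view(x, win, axis=0)
        # sw: (n - win + 1, C, win); partition along the window axis,
        # in frame blocks to bound the copy that np.partition makes
        block = max(1, int(5e7) // max(1, win * x.shape[1]))
        for lo in range(0, sw.shape[0], block):
            hi = min(lo + block, sw.shape[0])
            out[win - 1 + lo: win - 1 + hi] = (
                np.partition(sw[lo:hi], k, axis=2)[:, :, k]
            )
    return out


def _sliding_quantile_fenwick(x: np.ndarray, win: int, q: float) -> np.ndarray:
    """Order-statistic sweep with one Fenwick (BIT) counter per channel.

    Values are coordinate-compressed per channel; insert/remove/select are
    O(log n) per frame, vectorized across channels.
    """
    n, c = x.shape
    ranks = np.empty((n, c), dtype=np.int64)
    uniq = []
    for ch in range(c):
        u, inv = np.unique(x[:, ch], return_inverse=True)
        uniq.append(u)
        ranks[:, ch] = inv + 1  # 1-indexed
    size = 1
    while size < max(len(u) for u in uniq):
        size *= 2
    tree = np.zeros((c, size + 1), dtype=np.int64)
    chs = np.arange(c)
    steps = [1 << b for b in range(size.bit_length() - 1, -1, -1)]

    def update(idx, delta):
        i = idx.copy()
        active = i <= size
        while active.any():
            tree[chs[active], i[active]] += delta
            i[active] += i[active] & (-i[active])
            active = i <= size

    out = np.empty_like(x)
    uniq_pad = np.full((c, size), np.inf)
    for ch in range(c):
        uniq_pad[ch, : len(uniq[ch])] = uniq[ch]

    for t in range(n):
        update(ranks[t], 1)
        if t >= win:
            update(ranks[t - win], -1)
        m = min(t + 1, win)
        k = int(np.floor(q * (m - 1))) + 1  # 1-indexed k-th smallest
        pos = np.zeros(c, dtype=np.int64)
        rem = np.full(c, k, dtype=np.int64)
        for step in steps:
            npos = pos + step
            ok = npos <= size
            cnt = np.where(ok, tree[chs, np.minimum(npos, size)], 0)
            take = ok & (cnt < rem)
            pos = np.where(take, npos, pos)
            rem = np.where(take, rem - cnt, rem)
        out[t] = uniq_pad[chs, pos]
    return out


def sliding_low_quantile(x: np.ndarray, win: int, q: float) -> np.ndarray:
    """Causal running quantile of each column over a trailing window.

    ``out[t] = quantile(x[max(0, t - win + 1) : t + 1], q, method="lower")``
    evaluated per channel.  The window grows from a single frame during
    warm-up.  Output is bit-identical between the brute-force and
    Fenwick-tree paths.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("expected a (n_frames, n_channels) matrix")
    if win < 1:
        raise InvalidConfigError("window must span at least one frame")
    if win <= _BRUTE_MAX_WINDOW:
        return _sliding_quantile_brute(x, win, q)
    return _sliding_quantile_fenwick(x, win, q)


def slow_envelope(coch_levels: np.ndarray, frame_rate: float, tau: float,
                  percentile: float = DEFAULT_PERCENTILE) -> np.ndarray:
    """Slow background estimate of a level matrix at time constant ``tau``.

    A causal running low percentile over a ``tau``-long trailing window,
    clamped per cell to never exceed the input.  The clamp makes the
    residual (input minus envelope) a non-negative audibility and follows
    level drops immediately, as a background tracker should.
    """
    win = int(round(tau * frame_rate))
    if win < 1:
        raise InvalidConfigError(
            f"tau {tau} s is shorter than one frame at {frame_rate} frames/s"
        )
    if not 0.0 < percentile <= 0.5:
        raise InvalidConfigError("percentile must lie in (0, 0.5]")
    levels = np.asarray(coch_levels, dtype=float)
    env = sliding_low_quantile(levels, win, percentile)
    return np.minimum(env, levels)


# ---------------------------------------------------------------------------
# LayerSet

@dataclass
class LayerSet:
    """The four perceptual layers plus the slow envelopes that made them.

    ``second_fg``, ``minute_fg`` and ``hour_fg`` are audibilities in dB
    above the next slower level (>= 0 everywhere); ``hour_bg`` is the
    absolute slow level.  Their element-wise sum reproduces the source
    cochleogram exactly.
    """

    second_fg: np.ndarray
    minute_fg: np.ndarray
    hour_fg: np.ndarray
    hour_bg: np.ndarray
    slow_envelopes: dict
    taus: tuple
    percentile: float
    frame_rate: float
    center_freqs: np.ndarray
    floor_db: float
    calibration_offset: float
    warmup_frames: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.second_fg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.second_fg.shape[1]

    def layer(self, name: str) -> np.ndarray:
        if name not in LAYER_NAMES:
            raise InvalidInputError(f"unknown layer {name!r}; expected one of {LAYER_NAMES}")
        return getattr(self, name)

    @property
    def provisional(self) -> np.ndarray:
        """Boolean mask of frames whose slowest envelope lacks full history."""
        longest = max(self.warmup_frames.values()) if self.warmup_frames else 0
        mask = np.zeros(self.n_frames, dtype=bool)
        mask[: min(longest, self.n_frames)] = True
        return mask

    def validate(self) -> "LayerSet":
        shapes = {m.shape for m in (self.second_fg, self.minute_fg,
                                    self.hour_fg, self.hour_bg)}
        if len(shapes) != 1:
            raise InvalidInputError("layer matrices have mismatched shapes")
        for name in ("second_fg", "minute_fg", "hour_fg"):
            if np.min(getattr(self, name)) < -1e-9:
                raise InvalidInputError(f"{name} contains negative audibility")
        return self

    def save(self, dir_path) -> None:
        """One CSV per layer plus a JSON manifest, under ``dir_path``."""
        import json
        import os

        os.makedirs(dir_path, exist_ok=True)
        for name in LAYER_NAMES:
            np.savetxt(os.path.join(dir_path, name + ".csv"),
                       getattr(self, name), delimiter=",", fmt="%.6f")
        manifest = {
            "layers": list(LAYER_NAMES),
            "taus": list(self.taus),
            "percentile": self.percentile,
            "frame_rate": self.frame_rate,
            "center_freqs": list(map(float, self.center_freqs)),
            "floor_db": self.floor_db,
            "calibration_offset": self.calibration_offset,
            "warmup_frames": {str(k): int(v) for k, v in self.warmup_frames.items()},
            "meta": self.meta,
        }
        with open(os.path.join(dir_path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, dir_path) -> "LayerSet":
        import json
        import os

        with open(os.path.join(dir_path, "manifest.json")) as fh:
            man = json.load(fh)
        mats = {
            name: np.atleast_2d(
                np.loadtxt(os.path.join(dir_path, name + ".csv"), delimiter=",")
            )
            for name in LAYER_NAMES
        }
        return cls(
            **mats,
            slow_envelopes={},
            taus=tuple(man["taus"]),
            percentile=man["percentile"],
            frame_rate=man["frame_rate"],
            center_freqs=np.asarray(man["center_freqs"], dtype=float),
            floor_db=man["floor_db"],
            calibration_offset=man["calibration_offset"],
            warmup_frames={float(k): v for k, v in man["warmup_frames"].items()},
            meta=man.get("meta", {}),
        ).validate()


def decompose(coch: Cochleogram, taus=DEFAULT_TAUS,
              percentile: float = DEFAULT_PERCENTILE) -> LayerSet:
    """Split a cochleogram into the four perceptual layers.

    The cascade runs fast to slow; each slower envelope is estimated from
    the previous (clamped) envelope rather than the raw input, so the
    foregrounds are differences of successively slower estimates:

    ``second_fg = L - S_tau1``, ``minute_fg = S_tau1 - S_tau2``,
    ``hour_fg = S_tau2 - S_tau3``, ``hour_bg = S_tau3``.

    A recording shorter than the slowest tau is allowed: envelopes use the
    available history and the affected frames are flagged provisional.
    """
    coch.validate()
    taus = tuple(float(t) for t in taus)
    if len(taus) != 3 or not (taus[0] < taus[1] < taus[2]):
        raise InvalidConfigError("need three strictly increasing time constants")
    levels = np.asarray(coch.levels, dtype=float)

    envs = []
    src = levels
    for tau in taus:
        env = slow_envelope(src, coch.frame_rate, tau, percentile)
        envs.append(env)
        src = env
    s1, s2, s3 = envs

    return LayerSet(
        second_fg=levels - s1,
        minute_fg=s1 - s2,
        hour_fg=s2 - s3,
        hour_bg=s3,
        slow_envelopes={taus[0]: s1, taus[1]: s2, taus[2]: s3},
        taus=taus,
        percentile=percentile,
        frame_rate=coch.frame_rate,
        center_freqs=np.asarray(coch.center_freqs, dtype=float),
        floor_db=coch.floor_db,
        calibration_offset=coch.calibration_offset,
        warmup_frames={t: int(round(t * coch.frame_rate)) for t in taus},
        meta=dict(coch.meta),
    ).validate()


def reconstruct(layers: LayerSet) -> np.ndarray:
    """Element-wise sum of the four layers; equals the source levels."""
    mats = [layers.second_fg, layers.minute_fg, layers.hour_fg, layers.hour_bg]
    if len({m.shape for m in mats}) != 1:
        raise InvalidInputError("layer matrices have mismatched shapes")
    return mats[0] + mats[1] + mats[2] + mats[3]
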