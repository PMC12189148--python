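"""Local SNR and audibility-exceedance analysis for annoyance assessment.

The local SNR of a target against an environmental background is the
maximum over time-frequency cells of (target level - background level):
0 dB means the most audible target component has the same energy as the
background at that cell.  Aggregated per second over a long measurement,
the exceedance curve gives the fraction of time the target's audibility
was strictly above each threshold of a dB grid, annotated with the three
psychoacoustic reference levels: trained-listener detection at -5 dB,
effortful recognition at +5 dB, and dominance at +20 dB local SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .frontend import Cochleogram
from .layers import LayerSet

__all__ = [
    "AudibilityCurve",
    "REFERENCE_THRESHOLDS",
    "local_snr",
    "local_snr_series",
    "layer_audibility_series",
    "exceedance_curve",
    "plot_exceedance",
]

REFERENCE_THRESHOLDS = {
    "detection_trained": -5.0,
    "recognition": 5.0,
    "dominance": 20.0,
}

DEFAULT_THRESHOLDS = np.arange(-10.0, 31.0, 1.0)


@dataclass
class AudibilityCurve:
    """Fraction of seconds whose audibility strictly exceeds each threshold."""

    thresholds: np.ndarray
    fraction_exceeding: np.ndarray
    annotations: dict = field(default_factory=lambda: dict(REFERENCE_THRESHOLDS))

    def validate(self) -> "AudibilityCurve":
        f = np.asarray(self.fraction_exceeding, dtype=float)
        if f.shape != np.asarray(self.thresholds).shape:
            raise InvalidInputError("thresholds and fractions differ in shape")
        if f.size and (f.min() < 0 or f.max() > 1):
            raise InvalidInputError("fractions must lie in [0, 1]")
        if np.any(np.diff(f) > 1e-12):
            raise InvalidInputError("exceedance must be non-increasing")
        return self

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold_db": self.thresholds,
                             "fraction_exceeding": self.fraction_exceeding})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _check_axes(target: Cochleogram, background: Cochleogram) -> None:
    if target.levels.shape != background.levels.shape:
        raise InvalidInputError("target/background cochleogram shapes differ")
    if not np.allclose(target.center_freqs, background.center_freqs):
        raise InvalidInputError("target/background frequency axes differ")
    if target.frame_rate != background.frame_rate:
        raise InvalidInputError("target/background frame rates differ")


def local_snr(target: Cochleogram, background: Cochleogram, t: int) -> float:
    """Local SNR (dB) of second ``t``: max cell-wise level difference."""
    _check_axes(target, background)
    fr = target.frame_rate
    start, end = int(round(t * fr)), int(round((t + 1) * fr))
    end = min(end, target.n_frames)
    if t < 0 or start >= target.n_frames:
        raise InvalidInputError(f"second {t} outside recording")
    diff = target.levels[start:end] - background.levels[start:end]
    return float(diff.max())


def local_snr_series(target: Cochleogram, background: Cochleogram) -> np.ndarray:
    """Per-second local SNR over the whole recording."""
    _check_axes(target, background)
    n_seconds = int(target.n_frames // target.frame_rate)
    return np.array([local_snr(target, background, t) for t in range(n_seconds)])


def layer_audibility_series(layers: LayerSet, layer: str = "minute_fg") -> np.ndarray:
    """Per-second audibility of one foreground layer.

    Foreground layers already hold audibility in dB above the next slower
    level, so the per-second maximum over their cells is the local SNR of
    that layer against its own background estimate.
    """
    mat = layers.layer(layer)
    fr = layers.frame_rate
    n_seconds = int(mat.shape[0] // fr)
    out = np.empty(n_seconds)
    for t in range(n_seconds):
        out[t] = mat[int(round(t * fr)): int(round((t + 1) * fr))].max()
    return out


def exceedance_curve(audibility_per_second, thresholds=None) -> AudibilityCurve:
    """Fraction of seconds with audibility strictly above each threshold.

    Strict ``>``: a second exactly at a threshold does not exceed it.
    """
    series = np.asarray(audibility_per_second, dtype=float)
    if series.size == 0:
        raise InvalidInputError("empty audibility series")
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    thresholds = np.asarray(thresholds, dtype=float)
    frac = (series[None, :] > thresholds[:, None]).mean(axis=1)
    return AudibilityCurve(thresholds=thresholds,
                           fraction_exceeding=frac).validate()


def plot_exceedance(curves, path=None, ax=None, labels=None):
    """Plot one or more exceedance curves with the reference thresholds."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(curves, AudibilityCurve):
        curves = [curves]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for i, curve in enumerate(curves):
        label = labels[i] if labels else None
        ax.plot(curve.thresholds, curve.fraction_exceeding, lw=1.5, label=label)
    for name, x in REFERENCE_THRESHOLDS.items():
        ax.axvline(x, color="gray", ls="--", lw=0.8)
        ax.text(x, 1.01, name.replace("_", " "), rotation=45, fontsize=7,
                ha="left", va="bottom")
    ax.set_xlabel("local SNR threshold (dB)")
    ax.set_ylabel("fraction of time exceeding")
    ax.set_ylim(0, 1.05)
    if labels:
        ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
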