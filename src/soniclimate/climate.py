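"""Sonic climate: long-term aggregation of appraisals into a 2D histogram.

The climate histogram bins all per-second (pleasantness, eventfulness)
points on a [-1, 1] x [-1, 1] grid (default 21 x 21; an odd bin count keeps
the origin interior to a single central bin).  Derived summaries: quadrant
mass fractions, total-variation distance between two climates, and a
fraction-scaled rendering with percentile contours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .appraisal import AppraisalSeries
from .errors import InvalidInputError

__all__ = [
    "ClimateHistogram",
    "accumulate",
    "quadrant_fractions",
    "climate_distance",
    "merge",
    "plot_climate",
]

DEFAULT_BINS = 21
#: cumulative-mass contour levels used for display
CONTOUR_MASS = (0.5, 0.9, 0.99)


@dataclass
class ClimateHistogram:
    """Fractions per (pleasantness, eventfulness) bin over [-1, 1]^2.

    ``bins[i, j]`` is the fraction of appraisal seconds whose pleasantness
    fell in bin ``i`` and eventfulness in bin ``j``.  Bins are half-open
    ``[lo, hi)`` except the last bin on each axis, which is closed so that
    (1.0, 1.0) is counted.
    """

    bins: np.ndarray
    n_samples: int
    time_span: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.bins.shape[0]

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, self.n_bins + 1)

    def validate(self) -> "ClimateHistogram":
        b = np.asarray(self.bins, dtype=float)
        if b.ndim != 2 or b.shape[0] != b.shape[1]:
            raise InvalidInputError("bins must be a square matrix")
        if b.shape[0] < 3 or b.shape[0] % 2 == 0:
            raise InvalidInputError("bin count must be odd and >= 3")
        if b.size and b.min() < 0:
            raise InvalidInputError("negative bin fraction")
        if self.n_samples > 0 and abs(b.sum() - 1.0) > 1e-12:
            raise InvalidInputError("bin fractions must sum to 1")
        return self

    def save(self, path) -> None:
        payload = {
            "bins": self.bins.tolist(),
            "edges": self.edges.tolist(),
            "n_samples": int(self.n_samples),
            "time_span": self.time_span,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ClimateHistogram":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            bins=np.asarray(payload["bins"], dtype=float),
            n_samples=int(payload["n_samples"]),
            time_span=payload.get("time_span", {}),
        ).validate()


def accumulate(series: AppraisalSeries, n_bins: int = DEFAULT_BINS) -> ClimateHistogram:
    """Bin an appraisal series into a climate histogram.

    An empty series yields an all-zero histogram with ``n_samples = 0``.
    """
    if n_bins < 3 or n_bins % 2 == 0:
        raise InvalidInputError("n_bins must be odd and >= 3")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    n = len(series)
    if n == 0:
        return ClimateHistogram(np.zeros((n_bins, n_bins)), 0).validate()
    counts, _, _ = np.histogram2d(series.pleasantness, series.eventfulness,
                                  bins=(edges, edges))
    return ClimateHistogram(
        bins=counts / n,
        n_samples=n,
        time_span={"seconds": int(n)},
    ).validate()


def quadrant_fractions(hist: ClimateHistogram) -> dict:
    """Mass per circumplex quadrant, plus a center fraction.

    Bins whose span straddles zero on either axis (the central row and
    column, with an odd bin count) are assigned to ``center``; the rest go
    to the quadrant of their bin-center signs: calm (p>0, e<0), lively
    (p>0, e>0), chaotic (p<0, e>0), boring (p<0, e<0).  The five fractions
    sum to 1 for a populated histogram.
    """
    hist.validate()
    n = hist.n_bins
    mid = n // 2
    b = hist.bins
    center = b[mid, :].sum() + b[:, mid].sum() - b[mid, mid]
    pos_p, neg_p = slice(mid + 1, n), slice(0, mid)
    return {
        "calm": float(b[pos_p, neg_p].sum()),
        "lively": float(b[pos_p, pos_p].sum()),
        "chaotic": float(b[neg_p, pos_p].sum()),
        "boring": float(b[neg_p, neg_p].sum()),
        "center": float(center),
    }


def climate_distance(h1: ClimateHistogram, h2: ClimateHistogram) -> float:
    """Total variation distance between two climates, in [0, 1]."""
    if h1.n_bins != h2.n_bins:
        raise InvalidInputError("histograms have different bin counts")
    return float(0.5 * np.abs(h1.bins - h2.bins).sum())


def merge(h1: ClimateHistogram, h2: ClimateHistogram) -> ClimateHistogram:
    """Combine two climates, weighting each by its sample count."""
    if h1.n_bins != h2.n_bins:
        raise InvalidInputError("histograms have different bin counts")
    n = h1.n_samples + h2.n_samples
    if n == 0:
        return ClimateHistogram(np.zeros_like(h1.bins), 0).validate()
    bins = (h1.bins * h1.n_samples + h2.bins * h2.n_samples) / n
    return ClimateHistogram(bins=bins, n_samples=n).validate()


def _contour_levels(bins: np.ndarray, mass_levels=CONTOUR_MASS) -> list:
    """Bin-fraction thresholds containing each cumulative mass level."""
    flat = np.sort(bins.ravel())[::-1]
    cum = np.cumsum(flat)
    out = []
    for mass in mass_levels:
        idx = int(np.searchsorted(cum, mass))
        out.append(float(flat[min(idx, flat.size - 1)]))
    return out


def plot_climate(hist: ClimateHistogram, path=None, ax=None,
                 contour_mass=CONTOUR_MASS):
    """Render a climate histogram, color scaled by fraction per bin."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    edges = hist.edges
    mesh = ax.pcolormesh(edges, edges, hist.bins.T, cmap="viridis")
    centers = 0.5 * (edges[:-1] + edges[1:])
    levels = sorted(set(_contour_levels(hist.bins, contour_mass)))
    if hist.n_samples > 0 and len(levels) > 1:
        ax.contour(centers, centers, hist.bins.T, levels=levels,
                   colors="white", linewidths=0.8)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="gray", lw=0.8))
    ax.set_xlabel("pleasantness")
    ax.set_ylabel("eventfulness")
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    ax.set_aspect("equal")
    ax.figure.colorbar(mesh, ax=ax, label="fraction of time")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
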