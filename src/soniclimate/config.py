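"""Appraisal configuration: per-(layer, band) contribution rows.

Each row maps one perceptual layer restricted to one frequency band onto a
circumplex quadrant: the row's value (an audibility in dB, or an absolute
dB(A) level for the hour background) is scaled linearly to a weight in
[0, 1] within its value range, and pulls the per-second appraisal point
along that quadrant's diagonal.

The embedded defaults are the worked example set: hour background
30-70 dB(A) full band -> boring; hour foreground 0-20 dB split at 2300 Hz
-> boring / center; minute foreground 0-15 dB full band -> chaotic; second
foreground 0-20 dB split at 2300 Hz with a 5 s scope.  For the second
foreground the band-to-quadrant assignment is ambiguous in the source
material (the tabulated alignment reads low band -> calm, while the
descriptive text assigns high-frequency bird-like sounds to calm and the
human vocal band to lively); the default follows the descriptive reading
(``band_assignment="prose"``), and ``band_assignment="table"`` restores the
tabulated one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import InvalidConfigError

__all__ = ["ConfigRow", "AppraisalConfig", "default_config",
           "QUADRANTS", "LAYERS"]

QUADRANTS = ("calm", "lively", "chaotic", "boring", "center")
LAYERS = ("hour_bg", "hour_fg", "minute_fg", "second_fg")
UNITS = ("audibility_db", "level_dba")

DEFAULT_BAND_SPLIT = 2300.0
FULL_BAND = (20.0, 23000.0)


@dataclass
class ConfigRow:
    """One (layer, band) -> quadrant contribution rule."""

    layer: str
    band: tuple  # (f_lo, f_hi) in Hz
    value_range: tuple  # (v_min, v_max) in dB or dB(A)
    unit: str
    quadrant: str
    scope: float = 1.0  # look-back pooling window, seconds

    def validate(self, index: int | None = None) -> list:
        tag = f"row {index}" if index is not None else "row"
        problems = []
        if self.layer not in LAYERS:
            problems.append(f"{tag}: unknown layer {self.layer!r}")
        if self.quadrant not in QUADRANTS:
            problems.append(f"{tag}: unknown quadrant {self.quadrant!r}")
        if self.unit not in UNITS:
            problems.append(f"{tag}: unknown unit {self.unit!r}")
        if not self.value_range[0] < self.value_range[1]:
            problems.append(f"{tag}: value range min must be < max")
        if not self.band[0] < self.band[1]:
            problems.append(f"{tag}: band lower edge must be < upper edge")
        if self.scope < 1.0:
            problems.append(f"{tag}: scope must be >= 1 s")
        if self.layer == "hour_bg" and self.unit != "level_dba":
            problems.append(f"{tag}: hour_bg rows must use level_dba")
        if self.layer != "hour_bg" and self.unit != "audibility_db":
            problems.append(f"{tag}: foreground rows must use audibility_db")
        return problems


@dataclass
class AppraisalConfig:
    """Full appraisal parameter set.

    ``taus`` and ``percentile`` configure the layer decomposition that the
    rows consume; ``histogram_bins`` the sonic-climate grid.
    """

    rows: list = field(default_factory=list)
    band_split: float = DEFAULT_BAND_SPLIT
    taus: tuple = (1.0, 60.0, 3600.0)
    percentile: float = 0.10
    histogram_bins: int = 21

    def validate(self) -> "AppraisalConfig":
        problems = []
        if not self.rows:
            problems.append("config has no rows")
        for i, row in enumerate(self.rows):
            problems.extend(row.validate(i))
        if len(self.taus) != 3 or not (self.taus[0] < self.taus[1] < self.taus[2]):
            problems.append("taus must be three strictly increasing values")
        if not 0.0 < self.percentile <= 0.5:
            problems.append("percentile must lie in (0, 0.5]")
        if self.histogram_bins < 3 or self.histogram_bins % 2 == 0:
            problems.append("histogram_bins must be odd and >= 3")
        if problems:
            raise InvalidConfigError("; ".join(problems))
        return self

    # -- dict round-trip (YAML/JSON payload) -----------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["rows"] = [
            {**r, "band": list(r["band"]), "value_range": list(r["value_range"])}
            for r in d["rows"]
        ]
        d["taus"] = list(self.taus)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AppraisalConfig":
        base = default_config()
        rows = d.get("rows")
        if rows is not None:
            base.rows = [
                ConfigRow(
                    layer=r["layer"],
                    band=tuple(r["band"]),
                    value_range=tuple(r["value_range"]),
                    unit=r["unit"],
                    quadrant=r["quadrant"],
                    scope=float(r.get("scope", 1.0)),
                )
                for r in rows
            ]
        for key in ("band_split", "percentile", "histogram_bins"):
            if key in d:
                setattr(base, key, type(getattr(base, key))(d[key]))
        if "taus" in d:
            base.taus = tuple(float(t) for t in d["taus"])
        return base.validate()


def default_config(band_assignment: str = "prose",
                   taus=(1.0, 60.0, 3600.0)) -> AppraisalConfig:
    """The embedded example parameter set (see module docstring)."""
    if band_assignment not in ("prose", "table"):
        raise InvalidConfigError("band_assignment must be 'prose' or 'table'")
    split = DEFAULT_BAND_SPLIT
    low = (FULL_BAND[0], split)
    high = (split, FULL_BAND[1])
    if band_assignment == "prose":
        second_low_q, second_high_q = "lively", "calm"
    else:
        second_low_q, second_high_q = "calm", "lively"
    rows = [
        ConfigRow("hour_bg", FULL_BAND, (30.0, 70.0), "level_dba", "boring", 1.0),
        ConfigRow("hour_fg", low, (0.0, 20.0), "audibility_db", "boring", 1.0),
        ConfigRow("hour_fg", high, (0.0, 20.0), "audibility_db", "center", 1.0),
        ConfigRow("minute_fg", FULL_BAND, (0.0, 15.0), "audibility_db", "chaotic", 1.0),
        ConfigRow("second_fg", low, (0.0, 20.0), "audibility_db", second_low_q, 5.0),
        ConfigRow("second_fg", high, (0.0, 20.0), "audibility_db", second_high_q, 5.0),
    ]
    return AppraisalConfig(rows=rows, band_split=split,
                           taus=tuple(float(t) for t in taus)).validate()
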