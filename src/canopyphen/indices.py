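"""Canopy greenness color indices from daily mean RGB brightness.

Six indices computed from per-ROI daily mean channel brightness (R, G, B in
[0, 255]):

    GGR  = G / R                     ratio greenness index
    GCC  = G / (R + G + B)           green chromatic coordinate
    GEI  = 2G - (R + B)              green excess index
    RCC  = R / (R + G + B)           red chromatic coordinate
    GRVI = (G - R) / (G + R)         green-red vegetation index
    HUE  = HSV hue angle, degrees    piecewise on the maximal channel

Degenerate denominators (R = 0 for GGR, G + R = 0 for GRVI, R + G + B = 0 for
the chromatic coordinates, achromatic pixels for HUE) yield NaN for that day
rather than raising; downstream fitting treats NaN as a gap.

HUE follows the standard HSV convention (offsets 0/120/240 on whichever
channel attains the maximum, wrapped into [0, 360)).  ``hue_as_printed=True``
switches to a literal variant in which the red-maximum branch with G < B uses
a +340 offset instead of the 360 wrap, preserved for fidelity with an
alternative published constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INDEX_NAMES = ("GRVI", "HUE", "GGR", "RCC", "GCC", "GEI")


@dataclass
class IndexSeries:
    """A named color index sampled on a (possibly gappy) DOY grid."""

    roi: str
    index_name: str
    doys: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.doys = np.asarray(self.doys, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.doys.shape != self.values.shape:
            raise ValueError("doys and values must have equal length")
        if self.doys.size and np.any(np.diff(self.doys) <= 0):
            raise ValueError("doys must be strictly increasing")

    def __len__(self):
        return self.doys.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"roi": self.roi, "index": self.index_name,
                             "doy": self.doys, "value": self.values})


def _validate_rgb(r, g, b):
    for name, v in (("r", r), ("g", g), ("b", b)):
        if not np.all((np.asarray(v) >= 0) & (np.asarray(v) <= 255)):
            raise ValueError(f"channel {name} outside [0, 255]: {v}")


def _hue(r, g, b, as_printed: bool) -> float:
    i_max = max(r, g, b)
    i_min = min(r, g, b)
    if i_max == i_min:
        return float("nan")
    delta = i_max - i_min
    if g == i_max:
        return (b - r) / delta * 60.0 + 120.0
    if b == i_max:
        if as_printed:
            return (b - r) / delta * 60.0 + 240.0
        return (r - g) / delta * 60.0 + 240.0
    # red is the (strict) maximum
    if as_printed:
        return (g - b) / delta * 60.0 + (340.0 if g < b else 0.0)
    return ((g - b) / delta * 60.0) % 360.0


def compute_index(r: float, g: float, b: float, index_name: str,
                  hue_as_printed: bool = False) -> float:
    """One index value from mean channel brightness in [0, 255]."""
    _validate_rgb(r, g, b)
    name = index_name.upper()
    if name == "GGR":
        return g / r if r != 0 else float("nan")
    if name == "GCC":
        s = r + g + b
        return g / s if s != 0 else float("nan")
    if name == "RCC":
        s = r + g + b
        return r / s if s != 0 else float("nan")
    if name == "GEI":
        return 2.0 * g - (r + b)
    if name == "GRVI":
        return (g - r) / (g + r) if g + r != 0 else float("nan")
    if name == "HUE":
        return _hue(r, g, b, hue_as_printed)
    raise ValueError(f"unknown color index {index_name!r}; choose from {INDEX_NAMES}")


def compute_series(daily, index_names=INDEX_NAMES, hue_as_printed: bool = False):
    """Index series from a sequence of DailyRGB records.

    Returns one :class:`IndexSeries` per requested index, all sharing the
    daily records' DOY grid (gaps preserved).
    """
    daily = list(daily)
    if not daily:
        raise ValueError("daily RGB sequence is empty")
    names = [n.upper() for n in index_names]
    for n in names:
        if n not in INDEX_NAMES:
            raise ValueError(f"unknown color index {n!r}; choose from {INDEX_NAMES}")
    roi = daily[0].roi
    doys = np.array([d.doy for d in daily], dtype=int)
    out = []
    for n in names:
        vals = np.array([
            compute_index(d.mean_r, d.mean_g, d.mean_b, n, hue_as_printed)
            for d in daily
        ])
        n_missing = int(np.sum(~np.isfinite(vals)))
        if n_missing:
            logger.warning("index %s for ROI %s: %d day(s) degenerate, set to NaN",
                           n, roi, n_missing)
        out.append(IndexSeries(roi=roi, index_name=n, doys=doys, values=vals))
    return out


def series_to_csv(series_list, path):
    """Write the wide per-ROI CSV: roi, doy, grvi, hue, ggr, rcc, gcc, gei."""
    frames = {}
    for s in series_list:
        frames.setdefault(s.roi, {})[s.index_name.lower()] = pd.Series(s.values, index=s.doys)
    rows = []
    for roi, cols in frames.items():
        df = pd.DataFrame(cols)
        df.index.name = "doy"
        df.insert(0, "roi", roi)
        rows.append(df.reset_index())
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
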