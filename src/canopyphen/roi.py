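"""ROI extraction: per-image mean RGB over fixed pixel regions, daily means.

Images are timestamped camera frames of a canopy; each region of interest
(ROI) is a fixed rectangle or polygon in pixel coordinates over which the
mean brightness of each channel is taken, frame by frame.  Frames are then
averaged per calendar day (the "mean value method") to damp within-day
illumination variation, yielding one (R, G, B) triple per ROI per day.

Pixel convention: 0-based, rectangles are half-open [x0, x1) x [y0, y1) with
x horizontal (column) and y vertical (row).  Days with no frames are gaps,
never zero-filled; the fit stage accepts irregular DOY grids.  No image
registration is performed — frames are assumed pre-registered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import polygon as _sk_polygon

TIMESTAMP_RE = re.compile(r"(\d{8})[_-](\d{6})")


class TimestampError(ValueError):
    """Filename (and EXIF fallback) carry no parseable acquisition time."""


class GeometryError(ValueError):
    """ROI empty or outside the image bounds."""


@dataclass
class RGBImage:
    """One camera frame: three 8-bit channel arrays plus acquisition time."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    timestamp: datetime

    def __post_init__(self):
        if not (self.r.shape == self.g.shape == self.b.shape):
            raise ValueError("channel shapes differ")
        for ch in (self.r, self.g, self.b):
            if ch.min() < 0 or ch.max() > 255:
                raise ValueError("channel values outside [0, 255]")

    @property
    def height(self) -> int:
        return self.r.shape[0]

    @property
    def width(self) -> int:
        return self.r.shape[1]


@dataclass(frozen=True)
class ROISpec:
    """Named pixel region: rect (x0, y0, x1, y1), half-open, or polygon
    [(x, y), ...]."""

    name: str
    kind: str  # "rect" | "polygon"
    coords: tuple

    def mask(self, height: int, width: int) -> np.ndarray:
        if self.kind == "rect":
            x0, y0, x1, y1 = self.coords
            if not (0 <= x0 < x1 <= width and 0 <= y0 < y1 <= height):
                raise GeometryError(
                    f"ROI {self.name!r} rect {self.coords} outside {width}x{height} image")
            m = np.zeros((height, width), dtype=bool)
            m[y0:y1, x0:x1] = True
            return m
        if self.kind == "polygon":
            xs = np.array([p[0] for p in self.coords], dtype=float)
            ys = np.array([p[1] for p in self.coords], dtype=float)
            if xs.min() < 0 or ys.min() < 0 or xs.max() > width or ys.max() > height:
                raise GeometryError(
                    f"ROI {self.name!r} polygon outside {width}x{height} image")
            rr, cc = _sk_polygon(ys, xs, shape=(height, width))
            if rr.size == 0:
                raise GeometryError(f"ROI {self.name!r} polygon encloses no pixels")
            m = np.zeros((height, width), dtype=bool)
            m[rr, cc] = True
            return m
        raise ValueError(f"unknown ROI kind {self.kind!r}")


@dataclass(frozen=True)
class DailyRGB:
    """Per-ROI mean channel brightness for one calendar day."""

    roi: str
    date: object  # datetime.date
    doy: int
    mean_r: float
    mean_g: float
    mean_b: float
    n_images: int

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


def parse_timestamp(path) -> datetime:
    m = TIMESTAMP_RE.search(Path(path).stem)
    if m is None:
        raise TimestampError(f"no YYYYMMDD_HHMMSS timestamp in filename {path!r}")
    return datetime.strptime(m.group(1) + m.group(2), "%Y%m%d%H%M%S")


def load_image(path) -> RGBImage:
    """Read a PNG/JPEG frame; the timestamp comes from the filename, with an
    EXIF DateTimeOriginal fallback."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode not in ("RGB", "RGBA"):
                raise ValueError(
                    f"{path.name}: three color channels required, got mode {mode!r}")
            arr = np.asarray(im.convert("RGB"))
            exif = im.getexif()
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot decode image {path}: {exc}") from exc
    try:
        ts = parse_timestamp(path)
    except TimestampError:
        raw = exif.get(306) or exif.get(36867)  # DateTime / DateTimeOriginal
        if raw is None:
            raise TimestampError(
                f"no timestamp in filename or EXIF for {path.name}") from None
        ts = datetime.strptime(str(raw), "%Y:%m:%d %H:%M:%S")
    return RGBImage(r=arr[..., 0].astype(np.uint8), g=arr[..., 1].astype(np.uint8),
                    b=arr[..., 2].astype(np.uint8), timestamp=ts)


def mean_rgb(image: RGBImage, roi: ROISpec) -> tuple[float, float, float]:
    """Arithmetic mean of each channel over the ROI mask."""
    m = roi.mask(image.height, image.width)
    if not m.any():
        raise GeometryError(f"ROI {roi.name!r} contains no pixels")
    return (float(image.r[m].mean()), float(image.g[m].mean()),
            float(image.b[m].mean()))


def aggregate_daily(samples, roi: str):
    """Collapse per-frame (timestamp, r, g, b) samples to one mean per day.

    Days with no frames are simply absent from the output.  DOY is anchored
    to the year of the earliest sample and keeps increasing past day 365 for
    archives that span a year boundary, so downstream series stay strictly
    ordered.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to aggregate")
    df = pd.DataFrame(samples, columns=["timestamp", "mean_r", "mean_g", "mean_b"])
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    anchor = pd.Timestamp(df["date"].min()).replace(month=1, day=1)
    out = []
    for date, grp in df.groupby("date", sort=True):
        out.append(DailyRGB(
            roi=roi, date=date, doy=int((pd.Timestamp(date) - anchor).days) + 1,
            mean_r=float(grp["mean_r"].mean()), mean_g=float(grp["mean_g"].mean()),
            mean_b=float(grp["mean_b"].mean()), n_images=len(grp)))
    return out


def extract_archive(image_dir, rois, pattern="*.png"):
    """Run the whole extraction: directory of frames -> {roi: [DailyRGB]}."""
    paths = sorted(Path(image_dir).glob(pattern)) or sorted(Path(image_dir).glob("*.jpg"))
    if not paths:
        raise FileNotFoundError(f"no images matching {pattern} under {image_dir}")
    per_roi = {r.name: [] for r in rois}
    for p in paths:
        img = load_image(p)
        for r in rois:
            mr, mg, mb = mean_rgb(img, r)
            per_roi[r.name].append((img.timestamp, mr, mg, mb))
    return {name: aggregate_daily(samps, name) for name, samps in per_roi.items()}


def daily_to_csv(daily, path):
    pd.DataFrame([{
        "roi": d.roi, "date": d.date, "doy": d.doy, "mean_r": d.mean_r,
        "mean_g": d.mean_g, "mean_b": d.mean_b, "n_images": d.n_images,
    } for d in daily]).to_csv(path, index=False)
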