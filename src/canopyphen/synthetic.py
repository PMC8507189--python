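"""Seeded synthetic canopy archives and index series.

The study's camera archive (a Louisiana oak canopy photographed ~11 times a
day for 14 months) is not publicly deposited, so this module generates data
with the same statistical structure: a canopy region whose greenness follows
a double-logistic annual trajectory plus day-to-day Gaussian noise, static
non-vegetation regions (trunk, sky), within-day multiplicative illumination
jitter across the daily frames, and multiple ROIs with offset phenology.

Greenness is mapped to pixel color monotonically and invertibly:

    (R, G, B) = base_brown + s * (dR, dG, dB),   dG > 0,  dR, dB <= 0

with ``s`` solved per day so that the canopy GCC equals the requested
trajectory value; ground truth is therefore checkable to 8-bit quantization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .indices import IndexSeries
from .phenology import DoubleLogisticParams, evaluate_model
from .roi import ROISpec

# canopy color ramp: dormant brown -> green; GCC(base) = 1/3, monotone in s
_BASE_BROWN = np.array([120.0, 90.0, 60.0])
_RAMP = np.array([-60.0, 120.0, -30.0])


@dataclass(frozen=True)
class TrajectorySpec:
    """A double-logistic index trajectory on a DOY grid with Gaussian noise."""

    params: DoubleLogisticParams
    doy_start: int = 1
    doy_end: int = 365
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.doy_start <= self.doy_end <= 730:
            raise ValueError(
                f"doy range [{self.doy_start}, {self.doy_end}] must be a nonempty "
                "interval within [1, 730]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def doys(self) -> np.ndarray:
        return np.arange(self.doy_start, self.doy_end + 1)

    def truth(self) -> np.ndarray:
        """Noise-free trajectory (the recoverable ground truth)."""
        return evaluate_model(self.params, self.doys)


def generate_trajectory(spec: TrajectorySpec, roi: str = "roi1",
                        index_name: str = "GCC") -> IndexSeries:
    """Ground-truth curve plus i.i.d. Gaussian noise; seeded, reproducible."""
    rng = np.random.default_rng(spec.seed)
    values = spec.truth() + rng.normal(0.0, spec.noise_sd, spec.doys.size)
    return IndexSeries(roi=roi, index_name=index_name, doys=spec.doys, values=values)


@dataclass(frozen=True)
class SceneSpec:
    """Layout of the synthetic camera frame.

    Regions are half-open rectangles (x0, y0, x1, y1) in pixel coordinates;
    they must lie inside the frame and be pairwise disjoint.  ``images_per_day``
    frames are written per day on an hourly schedule starting 07:05 (the
    camera's daylight-only duty cycle); ``illumination_jitter`` is the sd of a
    per-frame lognormal brightness multiplier.
    """

    image_size: tuple[int, int] = (192, 108)  # (width, height)
    canopy_region: tuple[int, int, int, int] = (48, 10, 144, 70)
    trunk_region: tuple[int, int, int, int] = (80, 74, 112, 104)
    sky_region: tuple[int, int, int, int] = (0, 0, 40, 30)
    trunk_color: tuple[int, int, int] = (101, 67, 33)
    sky_color: tuple[int, int, int] = (135, 186, 235)
    background_color: tuple[int, int, int] = (90, 85, 80)
    images_per_day: int = 11
    illumination_jitter: float = 0.0

    def __post_init__(self):
        w, h = self.image_size
        regions = [self.canopy_region, self.trunk_region, self.sky_region]
        for reg in regions:
            x0, y0, x1, y1 = reg
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"region {reg} outside {w}x{h} frame")
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                if not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]):
                    raise ValueError(f"regions {a} and {b} overlap")
        if self.images_per_day < 1:
            raise ValueError("images_per_day must be >= 1")
        if self.illumination_jitter < 0:
            raise ValueError("illumination_jitter must be nonnegative")

    def rois(self) -> list[ROISpec]:
        return [ROISpec("canopy", "rect", self.canopy_region),
                ROISpec("trunk", "rect", self.trunk_region),
                ROISpec("sky", "rect", self.sky_region)]


def greenness_to_rgb(gcc: float) -> np.ndarray:
    """Invert GCC -> canopy RGB along the brown->green ramp (float, unclipped).

    Solves GCC((base + s*ramp)) = gcc for the ramp position s; the attainable
    GCC range with the default ramp is roughly [1/3, 0.55].
    """
    base_sum = _BASE_BROWN.sum()
    ramp_sum = _RAMP.sum()
    denom = _RAMP[1] - gcc * ramp_sum
    if denom <= 0:
        raise ValueError(f"requested GCC {gcc} not reachable on the color ramp")
    s = (gcc * base_sum - _BASE_BROWN[1]) / denom
    return _BASE_BROWN + s * _RAMP


def generate_image_archive(scene: SceneSpec, trajectory: TrajectorySpec,
                           out_dir, *, year: int = 2018, fmt: str = "png",
                           roi_name: str = "canopy") -> dict:
    """Write a timestamped frame archive whose canopy GCC tracks the trajectory.

    Returns a manifest (also written to ``manifest.json``) listing files and
    the ground-truth daily GCC; the truth is additionally saved as
    ``ground_truth.csv`` with columns (doy, value).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(trajectory.seed)
    series = generate_trajectory(trajectory, roi=roi_name)
    w, h = scene.image_size
    base = np.empty((h, w, 3), dtype=float)
    base[:] = scene.background_color
    x0, y0, x1, y1 = scene.sky_region
    base[y0:y1, x0:x1] = scene.sky_color
    x0, y0, x1, y1 = scene.trunk_region
    base[y0:y1, x0:x1] = scene.trunk_color

    anchor = date(year, 1, 1)
    files = []
    for doy, gcc in zip(series.doys, series.values):
        frame_date = anchor + timedelta(days=int(doy) - 1)
        canopy_rgb = greenness_to_rgb(float(gcc))
        for k in range(scene.images_per_day):
            frame = base.copy()
            x0, y0, x1, y1 = scene.canopy_region
            frame[y0:y1, x0:x1] = canopy_rgb
            if scene.illumination_jitter > 0:
                frame *= np.exp(rng.normal(0.0, scene.illumination_jitter))
            ts = datetime.combine(frame_date, time(7, 5)) + timedelta(hours=k)
            name = f"canopy_{ts:%Y%m%d_%H%M%S}.{fmt}"
            arr = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(out_dir / name)
            files.append({"path": name, "timestamp": ts.isoformat(), "doy": int(doy)})

    truth = pd.DataFrame({"doy": series.doys, "value": series.values})
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    manifest = {
        "n_files": len(files),
        "files": files,
        "images_per_day": scene.images_per_day,
        "rois": [{"name": r.name, "type": r.kind, "coords": list(r.coords)}
                 for r in scene.rois()],
        "ground_truth_csv": "ground_truth.csv",
        "true_params": {
            "w_min": trajectory.params.w_min, "w_max": trajectory.params.w_max,
            "s": trajectory.params.s, "a": trajectory.params.a,
            "m_s": trajectory.params.m_s, "m_a": trajectory.params.m_a,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def multi_roi_trajectories(base_params: DoubleLogisticParams, shifts_days,
                           doy_start=1, doy_end=365, noise_sd=0.0, seed=0,
                           index_name="GCC"):
    """Trajectories for several ROIs whose S/A inflections are shifted by the
    given day offsets — the micro-environment contrast between canopy
    positions."""
    out = []
    for i, shift in enumerate(shifts_days, start=1):
        p = DoubleLogisticParams(base_params.w_min, base_params.w_max,
                                 base_params.s + shift, base_params.a + shift,
                                 base_params.m_s, base_params.m_a)
        spec = TrajectorySpec(p, doy_start, doy_end, noise_sd, seed + i)
        out.append((spec, generate_trajectory(spec, roi=f"roi{i}", index_name=index_name)))
    return out
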