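"""Image-quality metrics: MSE, CoV%, CR%, line profiles and FWHM.

Conventions shared with the phantom geometry:

* ROIs are circles in the transaxial plane, specified by a world-frame
  centre (mm), a diameter (mm) and an inclusive slice range; voxel
  membership is by voxel-centre inclusion, matching the rasterizer.
* Contrast resolution CR% = 100 * |M - m| / M compares an object ROI
  mean ``m`` with the uniform-background mean ``M``; the magnitude
  convention makes hot objects report positive contrast (a relative
  activity of 4 on background 1 gives an ideal CR% of 300).
* FWHM is measured on a line profile against a baseline estimated from
  the outermost 10% of samples on each side (the phantom background is
  warm, so the half level must sit above background, not above zero);
  cold wells are inverted first; crossings are linearly interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError
from .phantom import ActivityVolume

__all__ = [
    "ROISpec",
    "ROIStats",
    "LineProfile",
    "mse",
    "roi_stats",
    "cov_percent",
    "contrast_resolution",
    "extract_profile",
    "fwhm",
]


@dataclass(frozen=True)
class ROISpec:
    """Circular transaxial ROI: centre (x, y) in mm, diameter in mm,
    inclusive slice index range."""

    center: tuple[float, float]
    diameter: float
    slice_range: tuple[int, int]

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidInputError("ROI diameter must be positive")
        if self.slice_range[0] > self.slice_range[1]:
            raise InvalidInputError("slice_range must be (low, high) inclusive")


@dataclass(frozen=True)
class ROIStats:
    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self):
        if self.n_pixels < 1:
            raise InvalidInputError("ROI must contain at least one voxel")
        if self.sd < 0:
            raise InvalidInputError("sd must be nonnegative")


@dataclass(frozen=True)
class LineProfile:
    """Sampled line profile with sample spacing in mm."""

    values: np.ndarray
    spacing: float
    thickness_pixels: int = 1

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) < 3:
            raise InvalidInputError("profile needs at least 3 samples")
        if self.spacing <= 0:
            raise InvalidInputError("spacing must be positive")


def mse(image_a, image_b) -> float:
    """Mean squared error between two equally shaped arrays."""
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def _roi_mask(volume: ActivityVolume, roi: ROISpec) -> np.ndarray:
    yy, xx = volume.plane_coords_mm()
    cx, cy = roi.center
    r = roi.diameter / 2.0
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def roi_stats(volume: ActivityVolume, roi: ROISpec) -> ROIStats:
    """Mean, sample SD (n-1 denominator) and voxel count inside an ROI.

    Voxels whose in-plane centre lies inside the circle are collected
    over the inclusive slice range.
    """
    lo, hi = roi.slice_range
    if hi >= volume.n_slices or lo < 0:
        raise InvalidInputError("slice_range outside the volume")
    mask = _roi_mask(volume, roi)
    if not mask.any():
        raise InvalidInputError("ROI contains no voxel centres")
    vals = volume.voxels[lo : hi + 1, mask].ravel()
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return ROIStats(mean=float(vals.mean()), sd=sd, n_pixels=int(vals.size))


def cov_percent(stats: ROIStats) -> float:
    """Percentage coefficient of variation, 100 * sd / mean."""
    if stats.mean <= 0:
        raise UndefinedMetricError("CoV% undefined for nonpositive mean")
    return 100.0 * stats.sd / stats.mean


def contrast_resolution(m_stats: ROIStats, M_stats: ROIStats) -> float:
    """Percentage contrast resolution 100 * |M - m| / M.

    ``M`` is the uniform-background ROI mean, ``m`` the object ROI mean.
    """
    if M_stats.mean <= 0:
        raise UndefinedMetricError("CR% undefined for nonpositive background mean")
    return 100.0 * abs(M_stats.mean - m_stats.mean) / M_stats.mean


def extract_profile(
    volume: ActivityVolume,
    start: tuple[float, float, int],
    end: tuple[float, float, int],
    thickness_pixels: int = 1,
) -> LineProfile:
    """Sample a straight in-plane line profile through a volume.

    ``start`` and ``end`` are (x mm, y mm, slice index) with equal slice
    index.  Samples are spaced one pixel apart along the line; the value
    at each sample is the mean over ``thickness_pixels`` parallel lines
    offset perpendicular to the main line, one pixel apart, centred on
    it.  Bilinear interpolation in the plane.
    """
    if thickness_pixels < 1:
        raise InvalidInputError("thickness must be >= 1")
    x0, y0, s0 = start
    x1, y1, s1 = end
    if s0 != s1:
        raise InvalidInputError("profile endpoints must lie in the same slice")
    if not 0 <= s0 < volume.n_slices:
        raise InvalidInputError("slice index outside the volume")
    length = math.hypot(x1 - x0, y1 - y0)
    if length <= 0:
        raise InvalidInputError("profile endpoints coincide")
    step = volume.voxel_size
    n_samples = int(round(length / step)) + 1
    ts = np.linspace(0.0, 1.0, n_samples)
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    px, py = -uy, ux  # unit perpendicular, in plane
    offs = (np.arange(thickness_pixels) - (thickness_pixels - 1) / 2.0) * step

    plane = volume.voxels[int(s0)]
    ny, nx = plane.shape

    def world_to_index(x_mm, y_mm):
        # inverse of the voxel-centre convention in ActivityVolume
        ix = x_mm / step + nx / 2.0 - 0.5
        iy = y_mm / step + ny / 2.0 - 0.5
        return iy, ix

    vals = np.zeros(n_samples)
    for off in offs:
        xs = x0 + ts * (x1 - x0) + off * px
        ys = y0 + ts * (y1 - y0) + off * py
        iy, ix = world_to_index(xs, ys)
        if np.any((ix < 0) | (ix > nx - 1) | (iy < 0) | (iy > ny - 1)):
            raise InvalidInputError("profile extends outside the volume")
        i0 = np.clip(np.floor(iy).astype(int), 0, ny - 2)
        j0 = np.clip(np.floor(ix).astype(int), 0, nx - 2)
        fy, fx = iy - i0, ix - j0
        vals += (
            plane[i0, j0] * (1 - fy) * (1 - fx)
            + plane[i0 + 1, j0] * fy * (1 - fx)
            + plane[i0, j0 + 1] * (1 - fy) * fx
            + plane[i0 + 1, j0 + 1] * fy * fx
        )
    vals /= thickness_pixels
    return LineProfile(values=vals, spacing=step, thickness_pixels=thickness_pixels)


def fwhm(profile: LineProfile) -> float:
    """Full width at half maximum of a line spread function, in mm.

    The baseline is the mean of the outermost 10% of samples on each
    side (at least one sample per side).  Valleys (cold objects) are
    inverted before measurement.  The half level is
    baseline + (peak - baseline) / 2; the two crossings nearest the peak
    are located by linear interpolation and their separation is returned
    in mm.
    """
    v = profile.values
    n = len(v)
    ntail = max(1, int(round(0.1 * n)))
    baseline = 0.5 * (v[:ntail].mean() + v[-ntail:].mean())

    centre = v[ntail:-ntail] if n > 2 * ntail else v
    up = centre.max() - baseline
    down = baseline - centre.min()
    if max(up, down) <= 0 or np.ptp(v) == 0:
        raise UndefinedMetricError("flat profile: no peak above the baseline")
    work = v if up >= down else 2 * baseline - v  # invert cold wells

    peak_idx = int(np.argmax(work[ntail:-ntail])) + ntail if n > 2 * ntail else int(np.argmax(work))
    peak = work[peak_idx]
    half = baseline + (peak - baseline) / 2.0

    def cross(idx_range):
        prev = peak_idx
        for i in idx_range:
            if work[i] <= half:
                # linear interpolation between i and the sample towards the peak
                lo, hi = work[i], work[prev]
                frac = (half - lo) / (hi - lo) if hi != lo else 0.0
                return i + frac * (prev - i)
            prev = i
        return None

    left = cross(range(peak_idx - 1, -1, -1))
    right = cross(range(peak_idx + 1, n))
    if left is None or right is None:
        raise UndefinedMetricError("profile does not cross the half level on both sides")
    return float((right - left) * profile.spacing)
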