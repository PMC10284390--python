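"""Oocyte geometry, radial phase-fraction profiles, density metrics, ROI
intensity series, and the voxel-count volume measurement.

Radial positions are normalized per angle: a pixel at distance d from the
oocyte center, in the direction where the boundary sits at R(θ), has
normalized radius d / R(θ).  R(θ) is measured on 72 rays at 5° increments
(angle 0 = animal pole, clockwise) and linearly interpolated in between.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .io import LineSpec, TimeLapse
from .segment import LabelFrame

N_ANGLES = 72          # 5° increments
HIST_BIN = 0.05        # cortical-granule radial histogram bin width


class GeometryError(ValueError):
    pass


@dataclass
class OocyteGeometry:
    center: tuple                 # (x, y) μm
    radius_by_angle: np.ndarray   # 72 values, μm
    animal_pole_angle: float = 0.0

    def __post_init__(self) -> None:
        self.radius_by_angle = np.asarray(self.radius_by_angle, dtype=float)
        if self.radius_by_angle.shape != (N_ANGLES,):
            raise ValueError(f"radius_by_angle must have {N_ANGLES} entries")
        if not (self.radius_by_angle > 0).all():
            raise ValueError("all radii must be > 0")

    def radius_at(self, angle_deg: np.ndarray) -> np.ndarray:
        """R(θ) by periodic linear interpolation; θ relative to the animal pole."""
        ang = np.mod(np.asarray(angle_deg, dtype=float), 360.0)
        grid = np.arange(0, 360 + 5, 5.0)
        vals = np.append(self.radius_by_angle, self.radius_by_angle[0])
        return np.interp(ang, grid, vals)

    @property
    def area(self) -> float:
        """Planar area enclosed by the boundary, μm² (polar integration)."""
        return float(0.5 * np.mean(self.radius_by_angle ** 2) * 2 * np.pi)


@dataclass
class PhaseProfile:
    bin_edges: np.ndarray                  # normalized radius, n_bins + 1
    fractions: pd.DataFrame                # n_bins x phases; NaN where unoccupied
    occupancy: np.ndarray                  # total phase pixels per bin


@dataclass
class DensityProfile:
    bin_edges: np.ndarray
    counts: np.ndarray
    surface_density: float                 # granule area / plane area, in [0, 1]


def _pixel_angle_dist(shape, center, pixel_size, animal_pole_angle=0.0):
    """Per-pixel (angle°, distance μm) relative to the center and animal pole."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dx = (xx + 0.5) * pixel_size - center[0]
    dy = (yy + 0.5) * pixel_size - center[1]
    # angle 0 points at the animal pole (up on screen), increasing clockwise
    ang = np.degrees(np.arctan2(dx, -dy)) - animal_pole_angle
    return np.mod(ang, 360.0), np.hypot(dx, dy)


def fit_geometry(mask: np.ndarray, pixel_size: float,
                 animal_pole_angle: float = 0.0) -> OocyteGeometry:
    """Center of mass + boundary distance along 72 rays at 5° increments."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("empty mask")
    com = ndi.center_of_mass(mask)
    center = ((com[1] + 0.5) * pixel_size, (com[0] + 0.5) * pixel_size)
    h, w = mask.shape
    max_r = np.hypot(h, w) * pixel_size
    step = pixel_size * 0.25
    ts = np.arange(0.0, max_r, step)
    radii = np.empty(N_ANGLES)
    for k in range(N_ANGLES):
        theta = np.radians(k * 5.0 + animal_pole_angle)
        ux, uy = np.sin(theta), -np.cos(theta)
        xs = (center[0] + ts * ux) / pixel_size - 0.5
        ys = (center[1] + ts * uy) / pixel_size - 0.5
        inside = (xs >= -0.5) & (xs < w - 0.5) & (ys >= -0.5) & (ys < h - 0.5)
        vals = np.zeros(len(ts), dtype=bool)
        vals[inside] = mask[np.clip(np.round(ys[inside]).astype(int), 0, h - 1),
                            np.clip(np.round(xs[inside]).astype(int), 0, w - 1)]
        hits = np.flatnonzero(vals)
        if len(hits) == 0:
            raise GeometryError(f"ray at {k * 5}° misses the mask boundary")
        radii[k] = ts[hits[-1]]
    return OocyteGeometry(center, radii, animal_pole_angle)


def phase_fractions(phases: Dict[str, np.ndarray], geometry: OocyteGeometry,
                    pixel_size: float, n_bins: int = 20) -> PhaseProfile:
    """Per-bin area fraction of each phase over normalized radius.

    Each phase pixel is assigned r/R(θ) using its own angle's boundary
    radius; within each occupied bin the fractions are normalized to the
    total of all phases, so they sum to 1.  Unoccupied bins are NaN.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    names = list(phases)
    if not names:
        raise ValueError("no phases given")
    shape = np.asarray(phases[names[0]]).shape
    ang, dist = _pixel_angle_dist(shape, geometry.center, pixel_size,
                                  geometry.animal_pole_angle)
    rnorm = dist / geometry.radius_at(ang)
    tol = pixel_size / geometry.radius_by_angle.min()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.zeros((n_bins, len(names)))
    total_any = 0
    for p_i, name in enumerate(names):
        ph = np.asarray(phases[name]).astype(bool)
        if ph.shape != shape:
            raise ValueError("phase images must share a common shape")
        sel = ph & (rnorm <= 1.0 + tol)
        total_any += sel.sum()
        idx = np.clip((rnorm[sel] * n_bins).astype(int), 0, n_bins - 1)
        counts[:, p_i] += np.bincount(idx, minlength=n_bins)
    if total_any == 0:
        raise ValueError("all-background input: no phase pixels inside the oocyte")
    occupancy = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / occupancy[:, None]
    frac[occupancy == 0] = np.nan
    return PhaseProfile(edges, pd.DataFrame(frac, columns=names), occupancy)


def delta_phase(a: PhaseProfile, b: PhaseProfile) -> pd.DataFrame:
    """Per-bin fraction change b − a (NaN wherever either is unoccupied)."""
    if not np.allclose(a.bin_edges, b.bin_edges):
        raise ValueError("profiles use different binning")
    if list(a.fractions.columns) != list(b.fractions.columns):
        raise ValueError("profiles cover different phases")
    return b.fractions - a.fractions


def radial_histogram(cortical: LabelFrame, geometry: OocyteGeometry) -> DensityProfile:
    """Histogram of granule-centroid normalized radii (bin width 0.05) and
    the surface density = total granule area / plane area."""
    px = cortical.pixel_size
    edges = np.arange(0.0, 1.10001 + HIST_BIN, HIST_BIN)
    rps = regionprops(cortical.labels)
    rnorms = []
    for rp in rps:
        cy, cx = rp.centroid
        x, y = (cx + 0.5) * px, (cy + 0.5) * px
        dx, dy = x - geometry.center[0], y - geometry.center[1]
        ang = np.mod(np.degrees(np.arctan2(dx, -dy)) - geometry.animal_pole_angle, 360.0)
        rnorms.append(np.hypot(dx, dy) / geometry.radius_at(np.array([ang]))[0])
    counts, _ = np.histogram(rnorms, bins=edges)
    area = (cortical.labels > 0).sum() * px * px
    return DensityProfile(edges, counts, surface_density=float(area / geometry.area))


# ---------------------------------------------------------------------------
# ROI intensity series / profiles
# ---------------------------------------------------------------------------

NORMALIZATIONS = ("none", "to_first", "to_reference_frame", "to_AP_value",
                  "subtract_baseline_then_peak")


def _band_profile(stack: np.ndarray, line: LineSpec, pixel_size: float) -> np.ndarray:
    """(T, positions) mean intensity across the band width, bilinear sampling."""
    from .kymo import _line_samples
    coords = _line_samples(line, pixel_size, stack.shape[-2:])
    T = stack.shape[0]
    out = np.empty((T, coords.shape[1]))
    for t in range(T):
        vals = ndi.map_coordinates(stack[t].astype(float), coords.reshape(2, -1),
                                   order=1, mode="nearest")
        out[t] = vals.reshape(coords.shape[1:]).mean(axis=1)
    return out


def roi_intensity(tl: TimeLapse, roi, channel: str,
                  normalization: str = "none",
                  reference_frame: int = 0) -> np.ndarray:
    """Mean intensity in a rectangle (per frame) or along a line band
    (per frame and position), with the requested normalization.

    ``roi`` is either (x0, y0, x1, y1) in μm or a :class:`LineSpec`.
    Normalizations: "none"; "to_first" (divide by the first frame);
    "to_reference_frame" (divide by the given frame); "to_AP_value"
    (divide each profile by its value at position 0); and
    "subtract_baseline_then_peak" (subtract the reference-frame profile,
    then scale each profile to its own maximum).
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {normalization!r}")
    stack = tl.channel(channel).astype(float)
    px = tl.pixel_size
    if isinstance(roi, LineSpec):
        series = _band_profile(stack, roi, px)         # (T, P)
    else:
        x0, y0, x1, y1 = roi
        j0, j1 = sorted((int(x0 / px), int(np.ceil(x1 / px))))
        i0, i1 = sorted((int(y0 / px), int(np.ceil(y1 / px))))
        h, w = stack.shape[-2:]
        if not (0 <= i0 < i1 <= h and 0 <= j0 < j1 <= w):
            raise ValueError("ROI is empty or exits the frame")
        series = stack[:, i0:i1, j0:j1].mean(axis=(1, 2))
    if normalization == "none":
        return series
    if normalization == "to_first":
        return series / series[0]
    if normalization == "to_reference_frame":
        return series / series[reference_frame]
    if series.ndim != 2:
        raise ValueError(f"{normalization} requires a line-band profile")
    if normalization == "to_AP_value":
        return series / series[:, :1]
    # subtract_baseline_then_peak
    sub = series - series[reference_frame]
    peak = sub.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(peak > 0, sub / peak, np.nan)
    return out


def voxel_volume(stack: np.ndarray, pixel_size: float, z_step: float) -> float:
    """Volume of a binary z-stack as voxel count × pixel_size² × z_step (μm³)."""
    stack = np.asarray(stack)
    if not z_step > 0:
        raise ValueError("z_step must be > 0")
    vals = np.unique(stack)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("stack must be binary (0/1)")
    return float(stack.sum(dtype=np.int64)) * pixel_size ** 2 * z_step
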