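"""Kymographs along lines or circumferential arcs, and slope velocimetry.

A kymograph is a (position × time) matrix where each cell is the mean
intensity across the band width perpendicular to the line (radially, for
arcs), sampled bilinearly.  Speeds come from automated per-column feature
localization followed by a line fit: a half-max interface crossing for
edges (least squares) or the per-column intensity maximum for ridges
(robust repeated-median fit).  Sign convention: speeds are positive toward
increasing position coordinate, so orient lines radially outward to get
"outward positive / inward negative".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.stats import siegelslopes

from .io import LineSpec, TimeLapse


class FeatureAbsentError(ValueError):
    """The tracked feature was missing in too many kymograph columns."""


@dataclass
class ArcSpec:
    """Circumferential arc: center (x, y) μm, radius μm, angular range in degrees
    (0 = animal pole, clockwise), and an odd radial band width in pixels."""

    center: Tuple[float, float]
    radius: float
    theta_start: float = 0.0
    theta_end: float = 360.0
    width: int = 1

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("width must be an odd integer >= 1")
        if self.theta_end <= self.theta_start:
            raise ValueError("theta_end must exceed theta_start")

    @property
    def length(self) -> float:
        return self.radius * math.radians(self.theta_end - self.theta_start)


@dataclass
class Kymograph:
    matrix: np.ndarray          # (positions, time)
    um_per_row: float
    s_per_col: float
    line: Union[LineSpec, ArcSpec, None] = None

    @property
    def length_um(self) -> float:
        return self.matrix.shape[0] * self.um_per_row


@dataclass
class VelocityEstimate:
    speed: float                # μm/min, signed
    fit_quality: float          # R² in [0, 1]
    support: tuple              # ((row0, row1), (col0, col1)) used for the fit
    intercept: float = 0.0      # fitted feature position at t = 0, μm from row 0


def _line_samples(line: LineSpec, pixel_size: float, shape) -> np.ndarray:
    """Sampling coordinates (2, n_rows, width) in (row, col) pixel index space."""
    (x0, y0), (x1, y1) = line.endpoints
    L = line.length
    n_rows = max(2, int(round(L / pixel_size)))
    t = np.linspace(0.0, L, n_rows)
    ux, uy = (x1 - x0) / L, (y1 - y0) / L
    # perpendicular unit vector (for width averaging)
    px_, py_ = -uy, ux
    offs = (np.arange(line.width) - (line.width - 1) / 2) * pixel_size
    xs = x0 + t[:, None] * ux + offs[None, :] * px_
    ys = y0 + t[:, None] * uy + offs[None, :] * py_
    rows = ys / pixel_size - 0.5
    cols = xs / pixel_size - 0.5
    h, w = shape
    if rows.min() < -0.5 or rows.max() > h - 0.5 or cols.min() < -0.5 or cols.max() > w - 0.5:
        raise ValueError("line (including its width) exits the image")
    return np.stack([rows, cols])


def _arc_samples(arc: ArcSpec, pixel_size: float, shape) -> np.ndarray:
    n_rows = max(2, int(round(arc.length / pixel_size)))
    th = np.radians(np.linspace(arc.theta_start, arc.theta_end, n_rows))
    # angle 0 = animal pole (up on screen), clockwise
    ux, uy = np.sin(th), -np.cos(th)
    offs = (np.arange(arc.width) - (arc.width - 1) / 2) * pixel_size
    rr = arc.radius + offs
    xs = arc.center[0] + ux[:, None] * rr[None, :]
    ys = arc.center[1] + uy[:, None] * rr[None, :]
    rows = ys / pixel_size - 0.5
    cols = xs / pixel_size - 0.5
    h, w = shape
    if rows.min() < -0.5 or rows.max() > h - 0.5 or cols.min() < -0.5 or cols.max() > w - 0.5:
        raise ValueError("arc (including its width) exits the image")
    return np.stack([rows, cols])


def build_kymograph(tl: TimeLapse, channel: str,
                    line: Union[LineSpec, ArcSpec]) -> Kymograph:
    """Width-averaged kymograph of one channel along a line or arc."""
    stack = tl.channel(channel).astype(float)
    if isinstance(line, ArcSpec):
        coords = _arc_samples(line, tl.pixel_size, stack.shape[-2:])
    else:
        coords = _line_samples(line, tl.pixel_size, stack.shape[-2:])
    n_rows = coords.shape[1]
    mat = np.empty((n_rows, tl.n_frames))
    flat = coords.reshape(2, -1)
    for t in range(tl.n_frames):
        vals = ndi.map_coordinates(stack[t], flat, order=1, mode="nearest")
        mat[:, t] = vals.reshape(coords.shape[1:]).mean(axis=1)
    um_per_row = line.length / (n_rows - 1)
    return Kymograph(mat, um_per_row, tl.frame_interval, line)


def _edge_positions(sub: np.ndarray) -> np.ndarray:
    """Per-column half-max crossing (fractional row), tracking continuity."""
    lo, hi = sub.min(), sub.max()
    n_rows, n_cols = sub.shape
    if hi - lo <= 1e-12:
        return np.full(n_cols, np.nan)       # featureless: no interface
    level = (lo + hi) / 2.0
    pos = np.full(n_cols, np.nan)
    prev = None
    for c in range(n_cols):
        v = sub[:, c]
        s = v - level
        cross = np.flatnonzero(s[:-1] * s[1:] < 0)
        exact = np.flatnonzero(s == 0)
        cands = []
        for i in cross:
            frac = s[i] / (s[i] - s[i + 1])
            cands.append(i + frac)
        cands.extend(exact.tolist())
        if not cands:
            continue
        cands = np.asarray(cands, dtype=float)
        if prev is None:
            pos[c] = cands[0]
        else:
            pos[c] = cands[np.argmin(np.abs(cands - prev))]
        prev = pos[c]
    return pos


def _ridge_positions(sub: np.ndarray) -> np.ndarray:
    """Per-column intensity maximum with parabolic sub-pixel refinement."""
    idx = np.argmax(sub, axis=0)
    pos = idx.astype(float)
    n_rows = sub.shape[0]
    cols = np.arange(sub.shape[1])
    inner = (idx > 0) & (idx < n_rows - 1)
    i = idx[inner]
    c = cols[inner]
    y0, y1, y2 = sub[i - 1, c], sub[i, c], sub[i + 1, c]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    pos[inner] = i + np.clip(shift, -0.5, 0.5)
    return pos


def _fit_quality(x, y, slope, intercept) -> float:
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-12:
        return 1.0 if ss_res <= 1e-9 else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def extract_slope(k: Kymograph, roi: Optional[tuple] = None,
                  mode: str = "edge") -> VelocityEstimate:
    """Speed of a moving interface (``edge``) or bright trace (``ridge``).

    ``roi`` is (row0, row1, col0, col1) limiting the fit to a kymograph
    sub-rectangle (defaults to the whole matrix).  Raises
    :class:`FeatureAbsentError` when the feature is localizable in fewer
    than half of the columns.
    """
    if mode not in ("edge", "ridge"):
        raise ValueError("mode must be 'edge' or 'ridge'")
    r0, r1, c0, c1 = roi if roi is not None else (0, k.matrix.shape[0],
                                                  0, k.matrix.shape[1])
    if not (0 <= r0 < r1 <= k.matrix.shape[0] and 0 <= c0 < c1 <= k.matrix.shape[1]):
        raise ValueError("roi outside the kymograph")
    sub = k.matrix[r0:r1, c0:c1]
    pos = _edge_positions(sub) if mode == "edge" else _ridge_positions(sub)
    valid = np.isfinite(pos)
    if valid.sum() < max(2, 0.5 * len(pos)):
        raise FeatureAbsentError("feature absent in more than 50% of columns")
    t_min = (np.flatnonzero(valid) + c0) * k.s_per_col / 60.0
    y_um = pos[valid] * k.um_per_row
    if mode == "ridge":
        slope, intercept = siegelslopes(y_um, t_min)
    else:
        slope, intercept = np.polyfit(t_min, y_um, 1)
    r2 = _fit_quality(t_min, y_um, slope, intercept)
    return VelocityEstimate(speed=float(slope), fit_quality=r2,
                            support=((r0, r1), (c0, c1)),
                            intercept=float(intercept + r0 * k.um_per_row))


def flow_profile(k: Kymograph, trajectories: Sequence[tuple],
                 axis_length_um: Optional[float] = None,
                 mode: str = "ridge") -> pd.DataFrame:
    """Per-trajectory slope plotted at its normalized start position.

    ``trajectories`` is a sequence of kymograph ROIs (row0, row1, col0,
    col1); the start position of each is the fitted feature position at
    its first frame, normalized by the axis length (defaults to the
    kymograph length).  Returns a DataFrame with columns position (0 = AP,
    1 = VP for an AV-axis kymograph), speed (μm/min) and fit_quality.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    L = axis_length_um if axis_length_um is not None else k.length_um
    rows = []
    for roi in trajectories:
        est = extract_slope(k, roi, mode=mode)
        t0_min = roi[2] * k.s_per_col / 60.0
        start = est.intercept + est.speed * t0_min
        rows.append((start / L, est.speed, est.fit_quality))
    return pd.DataFrame(rows, columns=["position", "speed", "fit_quality"])


def wave_speed(k: Kymograph, threshold: Optional[float] = None,
               min_valid_frac: float = 0.5) -> float:
    """Front speed from the onset time at each kymograph position.

    The onset at a position is the first frame its intensity exceeds the
    threshold (default: halfway between the matrix minimum and maximum);
    a robust line is fitted to onset time vs position and the speed is the
    inverse slope in μm/min.  A simultaneous onset everywhere returns
    ``math.inf`` (documented sentinel); an undetectable front raises
    :class:`FeatureAbsentError`.
    """
    mat = k.matrix
    thr = threshold if threshold is not None else (mat.min() + mat.max()) / 2.0
    above = mat > thr
    has = above.any(axis=1)
    if has.sum() < max(2, min_valid_frac * mat.shape[0]):
        raise FeatureAbsentError("no detectable onset front")
    onset_col = np.argmax(above, axis=1)[has]
    pos_um = np.flatnonzero(has) * k.um_per_row
    t_min = onset_col * k.s_per_col / 60.0
    if np.ptp(t_min) == 0:
        return math.inf
    slope, _ = siegelslopes(t_min, pos_um)     # min per μm
    if abs(slope) < 1e-12:
        return math.inf
    return float(1.0 / slope)
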