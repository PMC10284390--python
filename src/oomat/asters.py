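"""Microtubule-aster detection and the Voronoi contraction-domain analysis.

Asters are detected as multi-scale Laplacian-of-Gaussian blobs.  For the
contraction analysis, every pixel of the initial filament-network mask is
assigned to the nearest cluster surviving at the final time point (exact
Euclidean distance; ties go to the lowest cluster label) — the Voronoi
partition of the network by the final clusters.  Each domain's linear size
ξ is its maximum axis-aligned extent restricted to the initial mask, so a
domain spanning the whole square patch reports the system size; ξ1 ≥ ξ2 are
the two largest.  In the local contraction regime ξ1 ≈ ξ2, while large-scale
contraction drives ξ1 toward the system size at the expense of ξ2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import blob_log
from skimage.measure import label as cc_label

from .io import TimeLapse

LARGE_SCALE_FRACTION = 0.7   # xi1 >= this fraction of the field => large-scale


@dataclass
class AsterTable:
    counts: pd.DataFrame                 # frame, count, [density per 1e5 μm²]
    spots: List[pd.DataFrame]            # per-frame (x, y, sigma) μm


@dataclass
class ContractionDomains:
    domain_labels: np.ndarray            # labels over the initial mask, 0 elsewhere
    domain_sizes: np.ndarray             # ξ per domain, μm, descending
    xi1: float
    xi2: float
    field_size: float
    mode: str                            # "local" | "large_scale"


def detect_asters(frame: np.ndarray, pixel_size: float,
                  min_sigma_um: float = 3.0, max_sigma_um: float = 10.0,
                  threshold_rel: float = 0.1,
                  mask: Optional[np.ndarray] = None) -> pd.DataFrame:
    """LoG blob detection; returns spot centroids (x, y μm) and scale sigma.

    The threshold is relative to the frame's intensity range, so rescaling
    the image by a constant leaves the detections unchanged.  Centroids are
    refined by an intensity-weighted mean in a ±2σ window.  When an oocyte
    ``mask`` is given, the exterior is flattened to the interior median so
    the cell boundary step cannot fire the blob detector.
    """
    frame = np.asarray(frame, dtype=float)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        frame = np.where(mask, frame, np.median(frame[mask]))
    rng_ = np.ptp(frame)
    if rng_ == 0:
        return pd.DataFrame(columns=["x", "y", "sigma"])
    norm = (frame - frame.min()) / rng_
    blobs = blob_log(norm, min_sigma=min_sigma_um / pixel_size,
                     max_sigma=max_sigma_um / pixel_size, num_sigma=6,
                     threshold=threshold_rel, overlap=0.5)
    rows = []
    h, w = frame.shape
    bg = np.median(norm)
    for by, bx, bs in blobs:
        win = int(np.ceil(2 * bs))
        i0, i1 = max(0, int(by) - win), min(h, int(by) + win + 1)
        j0, j1 = max(0, int(bx) - win), min(w, int(bx) + win + 1)
        patch = np.clip(norm[i0:i1, j0:j1] - bg, 0, None)
        tot = patch.sum()
        if tot > 0:
            yy, xx = np.mgrid[i0:i1, j0:j1]
            by = float((patch * yy).sum() / tot)
            bx = float((patch * xx).sum() / tot)
        rows.append(((bx + 0.5) * pixel_size, (by + 0.5) * pixel_size,
                     bs * pixel_size))
    if not rows:
        return pd.DataFrame(columns=["x", "y", "sigma"])
    df = pd.DataFrame(rows, columns=["x", "y", "sigma"])
    # non-maximum suppression at min separation = min_sigma
    keep = np.ones(len(df), dtype=bool)
    pts = df[["x", "y"]].values
    amps = [norm[min(h - 1, int(y / pixel_size)), min(w - 1, int(x / pixel_size))]
            for x, y in pts]
    order = np.argsort(amps)[::-1]
    for ii, a in enumerate(order):
        if not keep[a]:
            continue
        for b in order[ii + 1:]:
            if keep[b] and np.hypot(*(pts[a] - pts[b])) < min_sigma_um:
                keep[b] = False
    return df[keep].reset_index(drop=True)


def aster_counts(tl: TimeLapse, channel: str = "microtubule",
                 oocyte_area_series: Optional[Sequence[float]] = None,
                 mask: Optional[np.ndarray] = None,
                 **detect_kwargs) -> AsterTable:
    """Per-frame aster counts, plus density per 10⁵ μm² when areas are given."""
    if oocyte_area_series is not None and len(oocyte_area_series) != tl.n_frames:
        raise ValueError("oocyte_area_series length must match the frame count")
    spots = []
    counts = []
    for f in range(tl.n_frames):
        df = detect_asters(tl.channel(channel)[f], tl.pixel_size, mask=mask,
                           **detect_kwargs)
        spots.append(df)
        counts.append(len(df))
    table = pd.DataFrame({"frame": np.arange(tl.n_frames), "count": counts})
    if oocyte_area_series is not None:
        table["density_per_1e5um2"] = table["count"] / np.asarray(oocyte_area_series) * 1e5
    return AsterTable(table, spots)


def temporal_projection(tl: TimeLapse, channel: str,
                        t_range: Optional[Tuple[int, int]] = None):
    """Per-pixel max over time plus the frame index at which the max occurs."""
    stack = tl.channel(channel).astype(float)
    t0, t1 = t_range if t_range is not None else (0, stack.shape[0])
    if not (0 <= t0 < t1 <= stack.shape[0]):
        raise ValueError("empty or out-of-range projection window")
    sub = stack[t0:t1]
    return sub.max(axis=0), t0 + np.argmax(sub, axis=0)


def segment_network(frame: np.ndarray, threshold: Optional[float] = None,
                    min_area_px: int = 4) -> np.ndarray:
    """Binary filament-network / cluster mask: global threshold + min-area.

    The default threshold sits halfway between the background (1st
    percentile) and the brightest structures (99.9th percentile), which
    stays meaningful even when the foreground occupies only a few pixels
    (a fully contracted network), where histogram methods fail.
    """
    frame = np.asarray(frame, dtype=float)
    if threshold is None:
        lo, hi = np.percentile(frame, (1.0, 99.9))
        threshold = 0.5 * (lo + hi)
    mask = frame > threshold
    lab = cc_label(mask)
    if lab.max():
        areas = np.bincount(lab.ravel())
        keep = areas >= min_area_px
        keep[0] = False
        mask = keep[lab]
    return mask


def voronoi_assign(final_labels: np.ndarray) -> np.ndarray:
    """Nearest-cluster label for every pixel (exact EDT; ties -> lowest label)."""
    labs = np.unique(final_labels[final_labels > 0])
    if len(labs) == 0:
        raise ValueError("no final clusters")
    h, w = final_labels.shape
    best_d = np.full((h, w), np.inf)
    assign = np.zeros((h, w), dtype=np.int32)
    for lab in labs:                    # ascending => ties keep the lowest label
        d = ndi.distance_transform_edt(final_labels != lab)
        closer = d < best_d - 1e-9
        best_d = np.where(closer, d, best_d)
        assign = np.where(closer, lab, assign)
    return assign


def _extent_um(mask: np.ndarray, pixel_size: float) -> float:
    ys, xs = np.nonzero(mask)
    return max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1) * pixel_size


def contraction_domains(initial_mask: np.ndarray, final_mask: np.ndarray,
                        pixel_size: float,
                        field_size: Optional[float] = None) -> ContractionDomains:
    """Voronoi contraction-domain decomposition with ξ1/ξ2 extraction.

    Each final cluster is labeled, every initial-network pixel is assigned
    to its nearest cluster, and the linear size ξ of each domain (domain ∩
    initial mask) is measured; domains are classified ``large_scale`` when
    ξ1 reaches ≥ 70% of the field size (boundary inclusive), else ``local``.
    With a single domain, ξ2 = ξ1 by convention.
    """
    initial_mask = np.asarray(initial_mask).astype(bool)
    final_mask = np.asarray(final_mask).astype(bool)
    if initial_mask.shape != final_mask.shape:
        raise ValueError("masks must share a common shape")
    if not initial_mask.any():
        raise ValueError("empty initial network mask")
    final_labels = cc_label(final_mask)
    if final_labels.max() == 0:
        raise ValueError("no final clusters detected")
    assign = voronoi_assign(final_labels)
    domains = np.where(initial_mask, assign, 0).astype(np.int32)
    sizes = []
    for lab in np.unique(domains[domains > 0]):
        sizes.append(_extent_um(domains == lab, pixel_size))
    sizes = np.sort(np.asarray(sizes))[::-1]
    xi1 = float(sizes[0])
    xi2 = float(sizes[1]) if len(sizes) > 1 else xi1
    if field_size is None:
        field_size = max(initial_mask.shape) * pixel_size
    mode = "large_scale" if xi1 >= LARGE_SCALE_FRACTION * field_size else "local"
    return ContractionDomains(domains, sizes, xi1, xi2, float(field_size), mode)


def classify_contraction(d: ContractionDomains) -> str:
    """"large_scale" iff ξ1 ≥ 0.7 × field size (boundary inclusive), else "local"."""
    return "large_scale" if d.xi1 >= LARGE_SCALE_FRACTION * d.field_size else "local"
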