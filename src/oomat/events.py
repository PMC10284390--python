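"""Event-level summaries: fusion histograms, mean granule-area series,
cortical-granule depletion on egg activation, K⁺-vesicle counts, and the
chorion-elevation ratio."""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .segment import LabelFrame
from .track import TrackSet


class CircleDetectionError(ValueError):
    pass


def fusion_histogram(tracks: TrackSet, bin_minutes: float = 10.0,
                     frame_interval_s: float = 60.0,
                     subsample: Optional[int] = None, seed: int = 0):
    """Merge events binned by time (minutes).

    ``subsample`` restricts the count to fusions involving a random subset
    of that many tracks (seeded; subsets are nested, so a larger subsample
    never counts fewer events) — mirroring the practice of following only
    10–20 granules per oocyte.  Returns (counts, bin_edges_minutes).
    """
    if bin_minutes <= 0:
        raise ValueError("bin_minutes must be > 0")
    merges = tracks.merges
    total_min = (tracks.tracks.frame.max() if len(tracks.tracks) else 0) \
        * frame_interval_s / 60.0
    edges = np.arange(0.0, total_min + bin_minutes, bin_minutes)
    if len(edges) < 2:
        edges = np.array([0.0, bin_minutes])
    if len(merges) == 0:
        return np.zeros(len(edges) - 1, dtype=int), edges
    if subsample is not None:
        all_tracks = np.sort(tracks.tracks.track.unique())
        rng = np.random.default_rng(seed)
        chosen = set(rng.permutation(all_tracks)[:subsample].tolist())
        keep = merges.incoming.apply(lambda ids: any(t in chosen for t in ids))
        merges = merges[keep]
    t_min = merges.frame.values * frame_interval_s / 60.0
    counts, _ = np.histogram(t_min, bins=edges)
    return counts, edges


def mean_area_series(source: Union[TrackSet, Sequence[LabelFrame]]):
    """Per-frame mean granule cross-sectional area (μm²) and the
    final/initial area factor.  Frames with zero granules are NaN (masked);
    the factor uses the first and last frames that have granules."""
    if isinstance(source, TrackSet):
        df = source.tracks
        if len(df) == 0:
            raise ValueError("empty track set")
        series = df.groupby("frame").area_um2.mean()
        series = series.reindex(range(int(df.frame.max()) + 1))
    else:
        frames = list(source)
        if not frames:
            raise ValueError("no frames")
        vals = []
        for lf in frames:
            areas = np.bincount(lf.labels.ravel())[1:]
            areas = areas[areas > 0] * lf.pixel_size ** 2
            vals.append(areas.mean() if len(areas) else np.nan)
        series = pd.Series(vals)
    valid = series.dropna()
    if len(valid) == 0:
        raise ValueError("no frame contains granules")
    factor = float(valid.iloc[-1] / valid.iloc[0])
    return series, factor


def depletion_ratio(pre: LabelFrame, post: LabelFrame) -> float:
    """% of pre-activation granules with no overlapping post-activation
    granule (any shared pixel; no registration — the egg is mounted)."""
    pre_labels = pre.labels
    ids = np.unique(pre_labels[pre_labels > 0])
    if len(ids) == 0:
        raise ValueError("empty pre-activation granule set")
    if pre_labels.shape != post.labels.shape:
        raise ValueError("frames must share a field of view")
    survived = np.unique(pre_labels[(pre_labels > 0) & (post.labels > 0)])
    return 100.0 * (1.0 - len(survived) / len(ids))


def k_vesicle_counts(label_frames: Sequence[LabelFrame]) -> pd.Series:
    """Number of K⁺ vesicles per frame."""
    return pd.Series([lf.n_objects for lf in label_frames], name="k_count")


def chorion_ratio(frame: np.ndarray, min_radius_px: Optional[int] = None,
                  max_radius_px: Optional[int] = None,
                  distinct_frac: float = 0.08) -> float:
    """Chorion diameter / oocyte diameter from one brightfield frame.

    The two roughly concentric circular boundaries are found by edge
    detection plus circular Hough voting.  If only one circular boundary is
    detectable the boundaries are taken to be coincident (ratio 1.0); if
    none is found a :class:`CircleDetectionError` is raised.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    rmax = max_radius_px or int(0.49 * min(h, w))
    rmin = min_radius_px or max(5, int(0.15 * min(h, w)))
    if np.ptp(frame) == 0:
        raise CircleDetectionError("blank frame")
    edges = canny(frame / frame.max(), sigma=1.5)
    radii = np.arange(rmin, rmax + 1)
    h_spaces = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(
        h_spaces, radii, total_num_peaks=12, normalize=True)
    if len(accums) == 0 or accums[0] < 0.2:
        raise CircleDetectionError("fewer than one circular boundary found")
    r_first = rads[0]
    for acc, r in zip(accums[1:], rads[1:]):
        if acc < 0.2:
            break
        if abs(r - r_first) > distinct_frac * r_first:
            lo, hi = sorted((r_first, r))
            return float(hi / lo)
    return 1.0
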