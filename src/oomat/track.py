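"""Overlap-based label linking over time, recording merge (fusion) events.

Granules are large and slow relative to the frame interval, so a label in
frame t+1 is linked to whichever frame-t label it shares the most pixels
with.  When two or more tracks link into the same new label, the event is
recorded as a merge and the track with the largest overlap (ties: smaller
track id) survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .segment import LabelFrame


@dataclass
class TrackSet:
    """tracks: (track, frame, label, x, y, area_um2); merges: (frame, incoming, survivor)."""

    tracks: pd.DataFrame
    merges: pd.DataFrame

    @property
    def n_tracks(self) -> int:
        return int(self.tracks.track.nunique())


def _overlap_table(prev: np.ndarray, cur: np.ndarray) -> pd.DataFrame:
    """Pixel-overlap counts between nonzero labels of two label images."""
    m = (prev > 0) & (cur > 0)
    if not m.any():
        return pd.DataFrame(columns=["prev", "cur", "count"])
    codes = prev[m].astype(np.int64) * (cur.max() + 1) + cur[m]
    uniq, cnt = np.unique(codes, return_counts=True)
    return pd.DataFrame({
        "prev": uniq // (cur.max() + 1),
        "cur": uniq % (cur.max() + 1),
        "count": cnt,
    })


def track_labels(label_frames: Sequence[LabelFrame]) -> TrackSet:
    """Link LabelFrames of one class into tracks and merge events."""
    if len(label_frames) < 2:
        raise ValueError("need at least 2 frames to track")
    klass = label_frames[0].klass
    shape = label_frames[0].labels.shape
    for lf in label_frames:
        if lf.klass != klass:
            raise ValueError("all frames must be of the same class")
        if lf.labels.shape != shape:
            raise ValueError("label frames must share a common shape")

    track_rows: List[tuple] = []
    merge_rows: List[tuple] = []
    next_track = 1
    # label -> track mapping for the current frame
    lab2tr: dict = {}

    def emit(lf: LabelFrame, mapping: dict) -> None:
        px = lf.pixel_size
        for rp in regionprops(lf.labels):
            tr = mapping.get(rp.label)
            if tr is None:
                continue
            cy, cx = rp.centroid
            track_rows.append((tr, lf.frame_index, rp.label,
                               (cx + 0.5) * px, (cy + 0.5) * px,
                               rp.area * px * px))

    first = label_frames[0]
    for lab in np.unique(first.labels[first.labels > 0]):
        lab2tr[int(lab)] = next_track
        next_track += 1
    emit(first, lab2tr)

    for t in range(1, len(label_frames)):
        prev_lf, cur_lf = label_frames[t - 1], label_frames[t]
        ov = _overlap_table(prev_lf.labels, cur_lf.labels)
        # each previous label links to the new label of maximal overlap
        links: dict = {}   # new label -> list of (overlap, track)
        if len(ov):
            best = ov.sort_values(["prev", "count", "cur"],
                                  ascending=[True, False, True]).groupby("prev").head(1)
            for _, row in best.iterrows():
                tr = lab2tr.get(int(row["prev"]))
                if tr is None:
                    continue
                links.setdefault(int(row["cur"]), []).append((int(row["count"]), tr))
        new_map: dict = {}
        for lab in np.unique(cur_lf.labels[cur_lf.labels > 0]):
            lab = int(lab)
            incoming = links.get(lab, [])
            if not incoming:
                new_map[lab] = next_track
                next_track += 1
            elif len(incoming) == 1:
                new_map[lab] = incoming[0][1]
            else:
                # merge: survivor = largest overlap, ties -> smaller track id
                incoming.sort(key=lambda it: (-it[0], it[1]))
                survivor = incoming[0][1]
                new_map[lab] = survivor
                merge_rows.append((cur_lf.frame_index,
                                   tuple(sorted(tr for _, tr in incoming)),
                                   survivor))
        lab2tr = new_map
        emit(cur_lf, lab2tr)

    tracks = pd.DataFrame(track_rows,
                          columns=["track", "frame", "label", "x", "y", "area_um2"])
    merges = pd.DataFrame(merge_rows, columns=["frame", "incoming", "survivor"])
    return TrackSet(tracks=tracks, merges=merges)
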