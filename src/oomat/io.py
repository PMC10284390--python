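"""Calibrated time-lapse I/O: multi-page TIFF stacks with a JSON sidecar.

Pixel data travel as plain TIFF (dimension order T, C, Y, X); the physical
calibration (pixel size, frame interval, channel names, optional
animal-vegetal axis annotation) lives in a JSON sidecar with the same
basename, e.g. ``run.tif`` + ``run.json``.  Integer pixel data round-trip
bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE = 1.0     # μm, assumed when no sidecar is found
DEFAULT_FRAME_INTERVAL = 60.0  # s


@dataclass
class TimeLapse:
    """A calibrated multi-channel time-lapse.

    ``frames`` has shape (T, C, Y, X).  ``axis_annotation`` is the angle of
    the animal pole in degrees (0 = up, clockwise), or None if unknown.
    """

    frames: np.ndarray
    channel_names: List[str]
    pixel_size: float = DEFAULT_PIXEL_SIZE
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    axis_annotation: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError(f"frames must be 4D (T, C, Y, X), got {self.frames.shape}")
        if min(self.frames.shape) < 1:
            raise ValueError("all frame dimensions must be >= 1")
        if len(self.channel_names) != self.frames.shape[1]:
            raise ValueError("channel_names length must equal the channel axis")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """The (T, Y, X) stack of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}") from None
        return self.frames[:, idx]

    def as_float(self) -> "TimeLapse":
        """Copy with frames converted to float64 (analyses operate on floats)."""
        return TimeLapse(self.frames.astype(np.float64), list(self.channel_names),
                         self.pixel_size, self.frame_interval, self.axis_annotation)


@dataclass
class LineSpec:
    """A measurement line: two (x, y) endpoints in μm and an odd width in pixels."""

    endpoints: tuple
    width: int = 1

    def __post_init__(self) -> None:
        (x0, y0), (x1, y1) = self.endpoints
        if x0 == x1 and y0 == y1:
            raise ValueError("endpoints must be distinct")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("width must be an odd integer >= 1")

    @property
    def length(self) -> float:
        (x0, y0), (x1, y1) = self.endpoints
        return float(np.hypot(x1 - x0, y1 - y0))


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_timelapse(tl: TimeLapse, path) -> None:
    """Write TIFF + JSON sidecar. Lossless for integer pixel types."""
    if np.issubdtype(tl.frames.dtype, np.floating) and not np.isfinite(tl.frames).all():
        raise ValueError("refusing to write non-finite pixel values")
    path = Path(path)
    tifffile.imwrite(path, tl.frames, metadata={"axes": "TCYX"})
    sidecar = {
        "pixel_size_um": tl.pixel_size,
        "frame_interval_s": tl.frame_interval,
        "channel_names": list(tl.channel_names),
        "axis_annotation_deg": tl.axis_annotation,
        "shape": list(tl.frames.shape),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_timelapse(path) -> TimeLapse:
    """Read TIFF + sidecar.  A missing sidecar falls back to default
    calibration (1.0 μm, 60 s) with a logged warning; a sidecar whose shape
    disagrees with the pixel data is an error."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, None]
    elif frames.ndim == 3:
        frames = frames[:, None]
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        logger.warning("no sidecar %s; assuming pixel_size=%g μm, frame_interval=%g s",
                       sc_path, DEFAULT_PIXEL_SIZE, DEFAULT_FRAME_INTERVAL)
        return TimeLapse(frames, [f"ch{i}" for i in range(frames.shape[1])])
    sc = json.loads(sc_path.read_text())
    if "shape" in sc and tuple(sc["shape"]) != frames.shape:
        raise ValueError(
            f"sidecar shape {sc['shape']} does not match pixel data {frames.shape}")
    return TimeLapse(
        frames,
        channel_names=list(sc.get("channel_names",
                                  [f"ch{i}" for i in range(frames.shape[1])])),
        pixel_size=float(sc.get("pixel_size_um", DEFAULT_PIXEL_SIZE)),
        frame_interval=float(sc.get("frame_interval_s", DEFAULT_FRAME_INTERVAL)),
        axis_annotation=sc.get("axis_annotation_deg"),
    )
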