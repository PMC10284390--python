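"""Synthetic contraction series: a speckled filament network on a square
surface patch collapsing onto one (global mode) or several (local mode)
attractors, with the attractor-basin partition emitted as ground truth.

Because every speckle travels on a straight line toward its attractor, the
true contraction domain of a pixel is exactly the nearest-attractor basin,
which is what the Voronoi analysis should recover.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import TimeLapse
from .params import UINT16_GAIN, SceneParams
from .scene import GroundTruth, apply_noise

MIN_FOCUS_SPACING = 12.0    # μm between attractors; below this they are unresolvable
ARRIVAL_JITTER = 3.0        # μm stop distance, so final clusters are compact blobs


def _attractors(mode: str, n_foci: int, L: float) -> np.ndarray:
    if mode == "global":
        return np.array([[L / 2, L / 2]])
    if n_foci < 1:
        raise ValueError("n_foci must be >= 1")
    g = int(np.ceil(np.sqrt(n_foci)))
    spacing = L / g
    if spacing < MIN_FOCUS_SPACING:
        raise ValueError(
            f"{n_foci} foci cannot be separated on a {L} μm patch "
            f"(min spacing {MIN_FOCUS_SPACING} μm)")
    pts = [((j + 0.5) * spacing, (i + 0.5) * spacing)
           for i in range(g) for j in range(g)]
    return np.asarray(pts[:n_foci])


def generate_contraction_series(params: SceneParams, mode: str = "local",
                                n_foci: int = 9):
    """Render the contracting-network time-lapse and its ground truth.

    Returns (TimeLapse, GroundTruth); the ground truth carries the
    attractor-basin ``domain_map`` (labels over the initial network mask)
    and the contraction mode in ``meta``.
    """
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    p = params
    L = p.field_size
    px = p.pixel_size
    n = int(round(L / px))
    if n < 8:
        raise ValueError("pixel_size incompatible with the patch size")
    rng = np.random.default_rng((p.seed, 4241))

    noise_field = gaussian_filter(rng.standard_normal((n, n)), 2.0)
    thr = np.quantile(noise_field, 1.0 - p.network_coverage)
    init_mask = noise_field > thr
    ys, xs = np.nonzero(init_mask)
    pos0 = np.c_[(xs + 0.5) * px, (ys + 0.5) * px]      # particle = mask pixel center

    att = _attractors(mode, n_foci, L)
    d2 = ((pos0[:, None, :] - att[None, :, :]) ** 2).sum(axis=2)
    basin = np.argmin(d2, axis=1)                        # ties -> lowest index
    domain_map = np.zeros((n, n), dtype=np.int32)
    domain_map[ys, xs] = basin + 1

    targets = att[basin]
    vec = targets - pos0
    dist0 = np.hypot(vec[:, 0], vec[:, 1])
    unit = vec / np.maximum(dist0, 1e-9)[:, None]
    stop = rng.uniform(0.0, ARRIVAL_JITTER, len(pos0))

    frames = []
    for f in range(p.n_frames):
        travelled = p.contraction_speed * f * p.frame_interval / 60.0
        d = np.maximum(stop, dist0 - travelled)
        cur = targets - unit * d[:, None]
        img = np.zeros((n, n))
        jj = np.clip((cur[:, 0] / px).astype(int), 0, n - 1)
        ii = np.clip((cur[:, 1] / px).astype(int), 0, n - 1)
        np.add.at(img, (ii, jj), 1.0)
        img = 0.05 + 0.95 * np.minimum(img, 3.0) / 3.0 * (img > 0)
        if p.psf_sigma > 0:
            img = gaussian_filter(img, p.psf_sigma / px)
        frng = np.random.default_rng((p.seed, 10009, f))
        img = apply_noise(img, frng, p.photon_scale, p.read_noise_sigma)
        frames.append(np.clip(img * UINT16_GAIN, 0, 65535).astype(np.uint16))

    tl = TimeLapse(np.stack(frames)[:, None], ["microtubule"],
                   pixel_size=px, frame_interval=p.frame_interval)
    gt = GroundTruth(
        granule_tracks=pd.DataFrame(columns=["frame", "id", "kind", "x", "y", "radius"]),
        fusion_events=pd.DataFrame(columns=["frame", "parent1", "parent2", "child"]),
        aster_tracks=pd.DataFrame(columns=["frame", "id", "x", "y"]),
        true_velocities=pd.DataFrame(
            [("network_contraction", p.contraction_speed)],
            columns=["process", "speed_um_per_min"]),
        domain_map=domain_map,
        meta={"mode": mode, "n_foci": 1 if mode == "global" else n_foci,
              "attractors": att.tolist()},
    )
    return tl, gt
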