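"""Shared fixtures: small synthetic scenes reused across test modules.

All scenes are seeded and deterministic; session scope keeps the expensive
render/segment work to a single pass.
"""

import numpy as np
import pytest

import oomat
from oomat.segment import segment_granules, segment_oocyte


def disk_mask(shape, cx, cy, r, pixel_size=1.0):
    """Brute-force pixel-center-in-disk mask (independent oracle)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    xum = (xx + 0.5) * pixel_size
    yum = (yy + 0.5) * pixel_size
    return (xum - cx) ** 2 + (yum - cy) ** 2 <= r * r


@pytest.fixture(scope="session")
def small_params():
    """A 200 μm oocyte at the default granule density, 2 frames."""
    return oomat.SceneParams(oocyte_diameter=200, gv_diameter=49.3, n_yolk=33,
                             n_cg=66, n_rab11=20, n_frames=2, seed=2)


@pytest.fixture(scope="session")
def clean_scene(small_params):
    """Noiseless, PSF-free render of the small scene plus its mask."""
    p = small_params.noiseless()
    state = oomat.init_scene(p)
    frame = oomat.render_frame(state)
    chans = {n: frame[i] for i, n in enumerate(oomat.CHANNELS)}
    mask = segment_oocyte(np.maximum(chans["ooplasm"], chans["lysotracker"]))
    return p, state, chans, mask


@pytest.fixture(scope="session")
def noisy_scene(small_params):
    """Default-noise render of the small scene."""
    p = small_params
    state = oomat.init_scene(p)
    frame = oomat.render_frame(state)
    chans = {n: frame[i] for i, n in enumerate(oomat.CHANNELS)}
    mask = segment_oocyte(np.maximum(chans["ooplasm"], chans["lysotracker"]))
    return p, state, chans, mask


@pytest.fixture(scope="session")
def fusion_run():
    """Sparse noiseless maturation run with known fusion events, segmented
    and tracked end to end (yolk class)."""
    p = oomat.SceneParams(oocyte_diameter=240, gv_diameter=59.2, n_yolk=20,
                          n_cg=0, n_rab11=0, kplus_rate=0.0,
                          aster_density_peak=0.0, n_frames=25, gvbd_time=120.0,
                          fusion_rounds_mean=1.0, seed=11).noiseless()
    tl, gt = oomat.generate_timelapse(p)
    names = tl.channel_names
    mask = segment_oocyte(
        np.maximum(tl.frames[0, 0], tl.frames[0, 1]).astype(float))
    lfs = [segment_granules({n: tl.frames[f, i].astype(float)
                             for i, n in enumerate(names)},
                            "yolk", p.pixel_size, mask, frame_index=f)
           for f in range(p.n_frames)]
    ts = oomat.track_labels(lfs)
    return p, tl, gt, lfs, ts


@pytest.fixture(scope="session")
def default_gt():
    """Ground truth of a full default maturation run (tables only; frames
    are rendered lazily by the tests that need them)."""
    p = oomat.SceneParams(seed=1)
    state = oomat.init_scene(p)
    rows = []
    fusion = []
    n_logged = 0
    for f in range(p.n_frames):
        if f > 0:
            state = oomat.step_scene(state, p.frame_interval)
        live = np.flatnonzero(state.alive)
        for i in live:
            rows.append((f, int(state.ids[i]), str(state.kind[i]),
                         float(state.x[i]), float(state.y[i]), float(state.r[i])))
        for ev in state.fusion_log[n_logged:]:
            fusion.append((f, ev["parent1"], ev["parent2"], ev["child"]))
        n_logged = len(state.fusion_log)
    import pandas as pd

    granules = pd.DataFrame(rows, columns=["frame", "id", "kind", "x", "y", "radius"])
    events = pd.DataFrame(fusion, columns=["frame", "parent1", "parent2", "child"])
    return p, granules, events
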