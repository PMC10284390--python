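"""Synthetic-scene generator: construction, dynamics, rendering contracts."""

import numpy as np
import pandas as pd
import pytest

import oomat
from oomat.scene import ALLOWED_OVERLAP, PackingError, RenderError
from conftest import disk_mask


def tiny_params(**kw):
    base = dict(oocyte_diameter=120, gv_diameter=29.6, n_yolk=6, n_cg=12,
                n_rab11=0, kplus_rate=0.0, aster_density_peak=0.0,
                n_frames=3, seed=0)
    base.update(kw)
    return oomat.SceneParams(**base)


class TestInit:
    def test_counts_by_construction(self, small_params):
        state = oomat.init_scene(small_params)
        assert (state.kind == "yolk").sum() == small_params.n_yolk
        assert (state.kind == "cortical").sum() == small_params.n_cg

    def test_empty_scene_is_valid(self):
        p = tiny_params(n_yolk=0, n_cg=0)
        state = oomat.init_scene(p)
        assert state.alive.sum() == 0

    def test_same_seed_identical_tables(self, small_params):
        a = oomat.init_scene(small_params)
        b = oomat.init_scene(small_params)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.r, b.r) and np.array_equal(a.kind, b.kind)

    def test_overlap_bound_respected(self, small_params):
        s = oomat.init_scene(small_params)
        gran = (s.kind == "yolk") | (s.kind == "cortical")
        x, y, r = s.x[gran], s.y[gran], s.r[gran]
        from scipy.spatial import cKDTree
        pairs = cKDTree(np.c_[x, y]).query_pairs(2 * r.max(), output_type="ndarray")
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.hypot(x[i] - x[j], y[i] - y[j])
        depth = (r[i] + r[j]) - d
        allowed = ALLOWED_OVERLAP * np.minimum(r[i], r[j])
        assert (depth <= allowed + 0.01).all()

    def test_granules_inside_oocyte_and_outside_gv(self, small_params):
        p = small_params
        s = oomat.init_scene(p)
        cx, cy = p.center
        d = np.hypot(s.x - cx, s.y - cy)
        assert (d <= p.oocyte_radius - s.r + 1e-6).all()
        gvc_y = cy - (p.oocyte_radius - p.gv_radius)
        dg = np.hypot(s.x - cx, s.y - gvc_y)
        gran = (s.kind == "yolk") | (s.kind == "cortical")
        assert (dg[gran] > p.gv_radius - 1e-6).all()

    def test_packing_failure_signals(self):
        p = tiny_params(n_yolk=200)  # far beyond what a 120 μm disk can hold
        with pytest.raises(PackingError):
            oomat.init_scene(p)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            oomat.SceneParams(gv_diameter=700.0)
        with pytest.raises(ValueError):
            oomat.SceneParams(yolk_radius_range=(20.0, 8.0))
        with pytest.raises(ValueError):
            oomat.SceneParams(pixel_size=0.0)


class TestStep:
    def test_forced_fusion_radius_and_area_factor(self):
        """Two equal 10 μm granules fusing obey 3D volume conservation."""
        p = tiny_params(n_yolk=0, n_cg=0, gvbd_time=0.0, fusion_rounds_mean=8.0,
                        compaction_speed=0.0, n_frames=2)
        cx, cy = p.center
        yolk = [[cx - 9.0, cy, 10.0], [cx + 9.0, cy, 10.0]]  # in contact
        state = oomat.init_scene(p, yolk=yolk, cg=np.empty((0, 3)))
        state = oomat.step_scene(state, p.frame_interval)
        alive = state.alive_of("yolk")
        assert len(alive) == 1
        child_r = state.r[alive[0]]
        assert child_r == pytest.approx(2 ** (1 / 3) * 10, rel=1e-12)
        # child area over mean parent area = 2^(2/3)
        assert (child_r ** 2 / 10 ** 2) == pytest.approx(2 ** (2 / 3), rel=1e-12)
        assert np.isclose(state.x[alive[0]], cx) and np.isclose(state.y[alive[0]], cy)

    def test_volume_conservation_through_run(self, default_gt):
        p, granules, events = default_gt
        yg = granules[granules.kind == "yolk"]
        v = yg.groupby("frame").apply(lambda d: (d.radius ** 3).sum(),
                                      include_groups=False)
        assert np.allclose(v.values, v.values[0], rtol=1e-9)
        # every fused child's cubed radius equals the sum of its parents'
        by_frame_id = yg.set_index(["frame", "id"]).radius
        for _, ev in events.iterrows():
            child = by_frame_id.loc[(ev.frame, ev.child)]
            p1 = by_frame_id.loc[(ev.frame - 1, ev.parent1)]
            p2 = by_frame_id.loc[(ev.frame - 1, ev.parent2)]
            assert child ** 3 == pytest.approx(p1 ** 3 + p2 ** 3, rel=1e-9)

    def test_monotone_compaction(self, default_gt):
        """Volume-weighted mean Yg distance to center never increases after
        GVBD (fusion places children at the volume-weighted centroid, and
        advection is strictly inward); the plain mean decreases net."""
        p, granules, _ = default_gt
        cx, cy = p.center
        yg = granules[granules.kind == "yolk"].copy()
        yg["d"] = np.hypot(yg.x - cx, yg.y - cy)
        yg["w"] = yg.radius ** 3
        wmean = yg.groupby("frame").apply(
            lambda d: (d.d * d.w).sum() / d.w.sum(), include_groups=False)
        post = wmean[wmean.index * p.frame_interval >= p.gvbd_time]
        assert (np.diff(post.values) <= 1e-9).all()
        mean = yg.groupby("frame").d.mean()
        assert mean.iloc[-1] < mean.iloc[0]

    def test_cg_mean_radius_strictly_increases(self, default_gt):
        """Oracle: direct average of normalized radius over granule_tracks."""
        p, granules, _ = default_gt
        cx, cy = p.center
        cg = granules[granules.kind == "cortical"]
        r0 = np.hypot(cg[cg.frame == 0].x - cx, cg[cg.frame == 0].y - cy).mean()
        r1 = np.hypot(cg[cg.frame == p.n_frames - 1].x - cx,
                      cg[cg.frame == p.n_frames - 1].y - cy).mean()
        assert r1 / p.oocyte_radius > r0 / p.oocyte_radius

    def test_area_factor_matches_closed_form(self, default_gt):
        """Mean Yg area factor ≈ 2^(2·fusion_rounds_mean/3) (= 2 at default)."""
        p, granules, events = default_gt
        yg = granules[granules.kind == "yolk"]
        a0 = (yg[yg.frame == 0].radius ** 2).mean()
        a1 = (yg[yg.frame == p.n_frames - 1].radius ** 2).mean()
        expected = 2 ** (2 * p.fusion_rounds_mean / 3)
        assert a1 / a0 == pytest.approx(expected, rel=0.10)
        assert len(events) > 0

    def test_gvbd_after_run_end_freezes_dynamics(self):
        p = tiny_params(gvbd_time=1e9, n_frames=5)
        tl, gt = oomat.generate_timelapse(p)
        assert len(gt.fusion_events) == 0
        cg = gt.granule_tracks[gt.granule_tracks.kind == "cortical"]
        first = cg[cg.frame == 0].sort_values("id")
        last = cg[cg.frame == 4].sort_values("id")
        assert np.allclose(first[["x", "y"]].values, last[["x", "y"]].values)

    def test_cg_count_conserved_until_activation(self):
        p = tiny_params(gvbd_time=0.0, n_frames=6, activation_time=200.0,
                        cg_exocytosis_frac=1.0, frame_interval=60.0)
        tl, gt = oomat.generate_timelapse(p)
        cg = gt.granule_tracks[gt.granule_tracks.kind == "cortical"]
        counts = cg.groupby("frame").size()
        assert (counts.loc[:3] == p.n_cg).all()
        assert 4 not in counts.index  # all exocytosed when activation hits

    def test_step_requires_positive_dt(self, small_params):
        state = oomat.init_scene(small_params)
        with pytest.raises(ValueError):
            oomat.step_scene(state, 0.0)


class TestRender:
    def test_empty_scene_uniform(self):
        p = tiny_params(n_yolk=0, n_cg=0).noiseless()
        state = oomat.init_scene(p)
        img = oomat.render_frame(state)
        oo = img[0]
        interior = disk_mask(oo.shape, *p.center, p.oocyte_radius - 2)
        gvc = (p.center[0], p.center[1] - (p.oocyte_radius - p.gv_radius))
        gv = disk_mask(oo.shape, gvc[0], gvc[1], p.gv_radius + 2)
        assert np.allclose(oo[interior & ~gv], 1.0)
        exterior = ~disk_mask(oo.shape, *p.center, p.oocyte_radius + 2)
        assert np.allclose(oo[exterior], oo[exterior].flat[0])

    def test_single_granule_pixel_count_oracle(self):
        """Bright-disk pixel count equals the brute-force pixel-center test."""
        p = tiny_params(n_yolk=0, n_cg=0).noiseless()
        cx, cy = p.center
        state = oomat.init_scene(p, yolk=[[cx + 10.3, cy - 5.7, 9.0]],
                                 cg=np.empty((0, 3)))
        ly = oomat.render_frame(state)[1]
        bright = ly >= 1.0
        oracle = disk_mask(ly.shape, cx + 10.3, cy - 5.7, 9.0)
        assert bright.sum() == oracle.sum()
        assert (bright == oracle).all()

    def test_render_determinism(self, small_params):
        state = oomat.init_scene(small_params)
        a = oomat.render_frame(state)
        b = oomat.render_frame(state)
        assert np.array_equal(a, b)

    def test_incompatible_pixel_size(self):
        p = tiny_params(pixel_size=50.0)
        state = oomat.init_scene(p)
        with pytest.raises(RenderError):
            oomat.render_frame(state)


class TestTimelapse:
    def test_single_frame_run(self):
        p = tiny_params(n_frames=1)
        tl, gt = oomat.generate_timelapse(p)
        assert tl.frames.shape[0] == 1
        assert len(gt.fusion_events) == 0

    def test_bit_identical_runs(self):
        p = tiny_params(n_frames=3)
        tl1, gt1 = oomat.generate_timelapse(p)
        tl2, gt2 = oomat.generate_timelapse(p)
        assert np.array_equal(tl1.frames, tl2.frames)
        pd.testing.assert_frame_equal(gt1.granule_tracks, gt2.granule_tracks)

    def test_frames_are_uint16(self):
        tl, _ = oomat.generate_timelapse(tiny_params(n_frames=2))
        assert tl.frames.dtype == np.uint16

    def test_ground_truth_consistent_with_frames(self):
        """Noiseless frames show each recorded granule as a dark disk in the
        ooplasm channel at its recorded position."""
        p = tiny_params(n_frames=3, gvbd_time=0.0).noiseless()
        tl, gt = oomat.generate_timelapse(p)
        for f in (0, 2):
            oo = tl.frames[f, 0].astype(float) / 10000.0
            sub = gt.granule_tracks[(gt.granule_tracks.frame == f)
                                    & (gt.granule_tracks.kind == "yolk")]
            for _, g in sub.iterrows():
                i, j = int(g.y / p.pixel_size), int(g.x / p.pixel_size)
                assert oo[i, j] < 0.2
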