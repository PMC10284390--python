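"""Geometry fitting, phase-fraction profiles, densities, ROIs, voxel volume."""

import numpy as np
import pandas as pd
import pytest

import oomat
from oomat.io import LineSpec, TimeLapse
from oomat.radial import (GeometryError, OocyteGeometry, delta_phase,
                          fit_geometry, phase_fractions, radial_histogram,
                          roi_intensity, voxel_volume, _pixel_angle_dist)
from oomat.segment import LabelFrame
from conftest import disk_mask


def make_disk_geometry(R=100.0, n=208):
    c = n / 2.0
    return OocyteGeometry((c, c), np.full(72, R)), (n, n), (c, c)


class TestGeometry:
    def test_disk_radii_within_one_pixel(self):
        mask = disk_mask((640, 640), 320.5, 320.5, 300.0)
        g = fit_geometry(mask, 1.0)
        assert np.abs(g.radius_by_angle - 300.0).max() <= 1.0
        assert np.hypot(g.center[0] - 320.5, g.center[1] - 320.5) <= 0.5

    def test_ellipse_matches_analytic_polar_radius(self):
        a, b = 300.0, 250.0   # x and y semi-axes
        yy, xx = np.mgrid[0:640, 0:640]
        mask = (((xx + 0.5 - 320.5) / a) ** 2 + ((yy + 0.5 - 320.5) / b) ** 2) <= 1
        g = fit_geometry(mask, 1.0)
        th = np.radians(np.arange(0, 360, 5))
        ux, uy = np.sin(th), -np.cos(th)     # angle 0 = animal pole (up)
        analytic = 1.0 / np.sqrt((ux / a) ** 2 + (uy / b) ** 2)
        assert np.abs(g.radius_by_angle - analytic).max() <= 1.0
        assert g.radius_by_angle[0] == pytest.approx(b, abs=1.0)
        assert g.radius_by_angle[18] == pytest.approx(a, abs=1.0)

    def test_empty_mask_errors(self):
        with pytest.raises(GeometryError):
            fit_geometry(np.zeros((10, 10), dtype=bool), 1.0)

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            OocyteGeometry((0, 0), np.full(10, 5.0))
        with pytest.raises(ValueError):
            OocyteGeometry((0, 0), np.zeros(72))


class TestPhaseFractions:
    def test_pure_yolk_is_one_everywhere(self):
        g, shape, c = make_disk_geometry()
        yolk = disk_mask(shape, c[0], c[1], 99.0)
        prof = phase_fractions({"yolk": yolk, "cortical": np.zeros(shape, bool)},
                               g, 1.0)
        occ = prof.occupancy > 0
        assert np.allclose(prof.fractions.yolk.values[occ], 1.0)
        assert np.isnan(prof.fractions.yolk.values[~occ]).all()

    def test_annulus_oracle_brute_force(self):
        """Cortical annulus at r/R ∈ [0.8, 0.9]: fractions equal a brute-force
        per-pixel binning to 1e-9, and are 1.0 exactly in those bins."""
        g, shape, c = make_disk_geometry()
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        d = np.hypot(xx + 0.5 - c[0], yy + 0.5 - c[1])
        annulus = (d >= 80.0) & (d < 90.0)
        interior = disk_mask(shape, c[0], c[1], 99.0)
        phases = {"ooplasm": interior & ~annulus, "cortical": annulus}
        prof = phase_fractions(phases, g, 1.0, n_bins=20)
        # brute force: loop pixels, same binning rule
        counts = np.zeros((20, 2))
        for name_i, name in enumerate(["ooplasm", "cortical"]):
            ys, xs = np.nonzero(phases[name])
            rn = np.hypot(xs + 0.5 - c[0], ys + 0.5 - c[1]) / 100.0
            keep = rn <= 1.0 + 1.0 / 100.0
            idx = np.clip((rn[keep] * 20).astype(int), 0, 19)
            counts[:, name_i] = np.bincount(idx, minlength=20)
        tot = counts.sum(axis=1)
        expect = np.where(tot[:, None] > 0, counts / np.maximum(tot[:, None], 1),
                          np.nan)
        got = prof.fractions[["ooplasm", "cortical"]].values
        occ = tot > 0
        assert np.allclose(got[occ], expect[occ], atol=1e-9)
        # bins fully inside the annulus are exactly 1.0 cortical
        assert prof.fractions.cortical.iloc[16] == pytest.approx(1.0, abs=1e-12)
        assert prof.fractions.cortical.iloc[17] == pytest.approx(1.0, abs=1e-12)
        assert prof.fractions.cortical.iloc[10] == 0.0

    def test_fractions_sum_to_one(self, clean_scene):
        p, state, chans, mask = clean_scene
        g = fit_geometry(mask, p.pixel_size)
        from oomat.segment import segment_granules
        yolk = segment_granules(chans, "yolk", p.pixel_size, mask).labels > 0
        cg = segment_granules(chans, "cortical", p.pixel_size, mask).labels > 0
        oop = mask & ~yolk & ~cg
        prof = phase_fractions({"ooplasm": oop, "yolk": yolk, "cortical": cg},
                               g, p.pixel_size)
        sums = prof.fractions.sum(axis=1).values
        occ = prof.occupancy > 0
        assert np.allclose(sums[occ], 1.0, atol=1e-9)

    def test_normalized_radius_within_bounds(self):
        g, shape, c = make_disk_geometry()
        ang, dist = _pixel_angle_dist(shape, g.center, 1.0)
        rn = dist / g.radius_at(ang)
        interior = disk_mask(shape, c[0], c[1], 100.0)
        assert rn[interior].max() <= 1.0 + 1.0 / 100.0 + 1e-9

    def test_delta_zero_and_antisymmetric(self, default_gt):
        p, granules, _ = default_gt
        g = OocyteGeometry(p.center, np.full(72, p.oocyte_radius))
        shape = (p.image_px, p.image_px)

        def masks_at(frame):
            out = {}
            for kind in ("yolk", "cortical"):
                m = np.zeros(shape, bool)
                sub = granules[(granules.frame == frame) & (granules.kind == kind)]
                for _, r in sub.iterrows():
                    m |= disk_mask(shape, r.x, r.y, r.radius)
                out[kind] = m
            interior = disk_mask(shape, *p.center, p.oocyte_radius)
            out["ooplasm"] = interior & ~out["yolk"] & ~out["cortical"]
            return out

        pa = phase_fractions(masks_at(0), g, p.pixel_size)
        pb = phase_fractions(masks_at(p.n_frames - 1), g, p.pixel_size)
        zero = delta_phase(pa, pa)
        assert np.nanmax(np.abs(zero.values)) == 0.0
        d_ab = delta_phase(pa, pb)
        d_ba = delta_phase(pb, pa)
        assert np.allclose(d_ab.values, -d_ba.values, equal_nan=True)
        # maturation signature: cortical fraction rises near the cortex and
        # falls in the interior; yolk rises centrally and falls at the rim
        assert np.nansum(d_ab.cortical.values[-4:]) > 0
        assert np.nansum(d_ab.cortical.values[:10]) < 0
        assert np.nansum(d_ab.yolk.values[:2]) > 0
        assert np.nansum(d_ab.yolk.values[-3:]) < 0

    def test_delta_binning_mismatch(self):
        g, shape, c = make_disk_geometry()
        m = disk_mask(shape, c[0], c[1], 90.0)
        a = phase_fractions({"yolk": m}, g, 1.0, n_bins=10)
        b = phase_fractions({"yolk": m}, g, 1.0, n_bins=20)
        with pytest.raises(ValueError):
            delta_phase(a, b)


class TestDensity:
    def test_empty_input(self):
        g, shape, _ = make_disk_geometry()
        lf = LabelFrame(np.zeros(shape, dtype=np.int32), "cortical")
        dp = radial_histogram(lf, g)
        assert dp.counts.sum() == 0
        assert dp.surface_density == 0.0

    def test_placed_granules_fall_in_expected_bin(self):
        g, shape, c = make_disk_geometry()
        labels = np.zeros(shape, dtype=np.int32)
        for k in range(10):
            ang = k * 0.6
            x = c[0] + 72.0 * np.sin(ang)
            y = c[1] - 72.0 * np.cos(ang)
            labels[int(y), int(x)] = k + 1
        dp = radial_histogram(LabelFrame(labels, "cortical"), g)
        bin_idx = int(0.72 / 0.05)
        assert dp.counts[bin_idx] == 10
        assert dp.counts.sum() == 10

    def test_density_equals_pixel_count_oracle(self):
        g, shape, c = make_disk_geometry()
        labels = np.zeros(shape, dtype=np.int32)
        m = disk_mask(shape, c[0] + 20, c[1], 6.0)
        labels[m] = 1
        dp = radial_histogram(LabelFrame(labels, "cortical"), g)
        assert dp.surface_density == pytest.approx(m.sum() / g.area, abs=1e-6)


class TestRoi:
    def make_tl(self, frames):
        return TimeLapse(np.asarray(frames, dtype=float)[:, None], ["c"])

    def test_uniform_value(self):
        tl = self.make_tl([np.full((20, 20), 7.0)])
        assert roi_intensity(tl, (2, 2, 10, 10), "c") == pytest.approx(7.0)

    def test_to_first(self):
        tl = self.make_tl([np.full((10, 10), v) for v in (2.0, 4.0, 6.0)])
        out = roi_intensity(tl, (1, 1, 8, 8), "c", "to_first")
        assert np.allclose(out, [1.0, 2.0, 3.0])

    def test_subtract_baseline_then_peak(self):
        """Circumference-like profile with a peak at the AP position."""
        n = 60
        base = np.zeros((n, n))
        after = np.zeros((n, n))
        xs = np.arange(n) + 0.5
        after[n // 2, :] = np.exp(-((xs - 5.0) ** 2) / 50.0)  # peak near x=5
        tl = self.make_tl([base, after])
        line = LineSpec(((0.5, n / 2 + 0.5), (n - 1.5, n / 2 + 0.5)), 1)
        prof = roi_intensity(tl, line, "c", "subtract_baseline_then_peak",
                             reference_frame=0)
        assert np.nanmax(prof[1]) == pytest.approx(1.0)
        assert np.nanargmax(prof[1]) <= 6
    def test_empty_roi_errors(self):
        tl = self.make_tl([np.zeros((10, 10))])
        with pytest.raises(ValueError):
            roi_intensity(tl, (8, 8, 8, 8), "c")

    def test_unknown_mode(self):
        tl = self.make_tl([np.zeros((10, 10))])
        with pytest.raises(ValueError):
            roi_intensity(tl, (0, 0, 5, 5), "c", "bogus")


class TestVoxelVolume:
    def test_single_voxel(self):
        stack = np.zeros((3, 4, 4), dtype=np.uint8)
        stack[1, 2, 2] = 1
        assert voxel_volume(stack, 1.0, 2.0) == pytest.approx(2.0)

    def test_digitized_ball(self):
        R = 50.0
        zz, yy, xx = np.mgrid[0:52, 0:52, 0:52]
        ball = ((xx + 0.5 - 26) ** 2 + (yy + 0.5 - 26) ** 2
                + (zz + 0.5 - 26) ** 2) <= (R / 2) ** 2
        vol = voxel_volume(ball.astype(np.uint8), 2.0, 2.0)
        assert vol == pytest.approx(4 / 3 * np.pi * R ** 3, rel=0.02)

    def test_empty_stack(self):
        assert voxel_volume(np.zeros((2, 3, 3), dtype=np.uint8), 1.0, 1.0) == 0.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            voxel_volume(np.full((2, 2, 2), 3, dtype=np.uint8), 1.0, 1.0)
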