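"""Synthetic oocyte-maturation scenes: initialization, dynamics, rendering.

Coordinates are in μm with the origin at the image top-left corner, x
rightward and y downward; pixel (i, j) has its center at
((j + 0.5) * pixel_size, (i + 0.5) * pixel_size).  Angle 0 points at the
animal pole (straight up on screen) and increases clockwise.

The simulated dynamics are prescribed kinematics, not a fluid-mechanical
model: yolk granules advect inward at a constant speed and fuse pairwise
with 3D volume conservation, cortical granules advect outward, microtubule
asters switch on in an animal-to-vegetal circumferential wave and drift
outward, and K⁺ vesicles appear after GV breakdown and later disappear.
Every run is bit-reproducible from (params, seed), and a :class:`GroundTruth`
record of all object tracks, fusion events, and true speeds is emitted
alongside the rendered frames so downstream measurements can be validated.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .io import TimeLapse
from .params import CHANNELS, UINT16_GAIN, SceneParams


class PackingError(RuntimeError):
    """Granules could not be placed at the requested density."""


class RenderError(ValueError):
    """The field of view would be degenerate at the requested pixel size."""


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generator-emitted tables used as test oracles.

    granule_tracks: (frame, id, kind, x, y, radius) for every live granule.
    fusion_events:  (frame, parent1, parent2, child).
    aster_tracks:   (frame, id, x, y).
    true_velocities: (process, speed_um_per_min); inward speeds are negative.
    domain_map:     label image of attractor basins (contraction series only).
    """

    granule_tracks: pd.DataFrame
    fusion_events: pd.DataFrame
    aster_tracks: pd.DataFrame
    true_velocities: pd.DataFrame
    domain_map: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def save(self, prefix) -> None:
        prefix = str(prefix)
        self.granule_tracks.to_csv(prefix + "_granule_tracks.csv", index=False)
        self.fusion_events.to_csv(prefix + "_fusion_events.csv", index=False)
        self.aster_tracks.to_csv(prefix + "_aster_tracks.csv", index=False)
        self.true_velocities.to_csv(prefix + "_true_velocities.csv", index=False)
        if self.domain_map is not None:
            import tifffile

            tifffile.imwrite(prefix + "_domain_map.tif",
                             self.domain_map.astype(np.uint16))


# ---------------------------------------------------------------------------
# scene state
# ---------------------------------------------------------------------------

@dataclass
class SceneState:
    params: SceneParams
    time: float
    ids: np.ndarray          # int64
    kind: np.ndarray         # unicode: yolk | cortical | kplus | rab11 | pocket
    x: np.ndarray
    y: np.ndarray
    r: np.ndarray
    alive: np.ndarray        # bool
    death_time: np.ndarray   # float, NaN = no scheduled death
    parents: Dict[int, Tuple[int, int]]
    asters: pd.DataFrame     # id, x0, y0, t_on, t_off, sigma, amplitude
    pockets: pd.DataFrame    # id, s0, lateral, speed (empty unless flow mode on)
    next_id: int
    fusion_log: List[dict]
    fusions_done: int
    target_fusions: int
    rng: np.random.Generator

    def copy(self) -> "SceneState":
        new = _copy.copy(self)
        for name in ("ids", "kind", "x", "y", "r", "alive", "death_time"):
            setattr(new, name, getattr(self, name).copy())
        new.parents = dict(self.parents)
        new.fusion_log = list(self.fusion_log)
        new.asters = self.asters.copy()
        new.pockets = self.pockets.copy()
        return new

    # convenience selectors ------------------------------------------------

    def alive_of(self, kind: str) -> np.ndarray:
        return np.flatnonzero(self.alive & (self.kind == kind))

    def active_asters(self) -> pd.DataFrame:
        """Asters alive at the current time, with drifted positions."""
        p = self.params
        a = self.asters
        if a.empty:
            return a.assign(x=[], y=[])
        on = (a.t_on.values <= self.time) & (self.time < a.t_off.values)
        a = a[on]
        cx, cy = p.center
        dx, dy = a.x0.values - cx, a.y0.values - cy
        d0 = np.hypot(dx, dy)
        d0 = np.where(d0 < 1e-9, 1e-9, d0)
        drift = p.aster_drift_speed * np.maximum(0.0, self.time - a.t_on.values) / 60.0
        clamp = p.oocyte_radius - 2.0 * p.aster_sigma
        d = np.minimum(clamp, d0 + drift)
        return pd.DataFrame({
            "id": a.id.values,
            "x": cx + dx / d0 * d,
            "y": cy + dy / d0 * d,
            "sigma": a.sigma.values,
            "amplitude": a.amplitude.values,
        })

    def pocket_positions(self) -> pd.DataFrame:
        """Current ooplasm-pocket positions (empty unless flow mode is on)."""
        p = self.params
        if self.pockets.empty:
            return pd.DataFrame(columns=["id", "x", "y"])
        cx, cy = p.center
        dt_min = max(0.0, self.time - p.gvbd_time) / 60.0
        s = np.maximum(5.0, self.pockets.s0.values - self.pockets.speed.values * dt_min)
        return pd.DataFrame({
            "id": self.pockets.id.values,
            "x": cx + self.pockets.lateral.values,
            "y": cy - p.oocyte_radius + s,
        })


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

ALLOWED_OVERLAP = 0.1   # pair overlap depth allowed, as a fraction of the smaller radius


def _relax(P, cur, R, center, gvc, gv_r, sweeps, push, rng, jitter):
    """Push-apart relaxation sweeps; returns (positions, worst residual excess)."""
    worst = np.inf
    cx, cy = center
    for _ in range(sweeps):
        tree = cKDTree(P)
        pairs = tree.query_pairs(2 * cur.max(), output_type="ndarray")
        disp = np.zeros_like(P)
        worst = 0.0
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            d = P[j] - P[i]
            dist = np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-9)
            tol = ALLOWED_OVERLAP * np.minimum(cur[i], cur[j])
            excess = (cur[i] + cur[j] - tol) - dist
            m = excess > 1e-6
            if m.any():
                worst = float(excess[m].max())
                u = d[m] / dist[m, None]
                step = push * excess[m, None] / 2 * u
                np.add.at(disp, i[m], -step)
                np.add.at(disp, j[m], step)
        if jitter > 0:
            disp = disp + rng.normal(0.0, jitter, P.shape)
        P = P + disp
        dc = np.hypot(P[:, 0] - cx, P[:, 1] - cy)
        out = dc > (R - cur)
        if out.any():
            scale = (R - cur[out]) / dc[out]
            P[out, 0] = cx + (P[out, 0] - cx) * scale
            P[out, 1] = cy + (P[out, 1] - cy) * scale
        dg = P - gvc
        dgd = np.maximum(np.hypot(dg[:, 0], dg[:, 1]), 1e-9)
        lim = gv_r + 0.9 * cur
        ing = dgd < lim
        if ing.any():
            P[ing] = gvc + dg[ing] * (lim[ing] / dgd[ing])[:, None]
        if worst < 1e-3 and jitter == 0:
            break
    return P, worst


def _pack_yolk(rng, radii, R, center, gvc, gv_r):
    """Growth-and-relaxation packing of the large granules."""
    n = len(radii)
    cx, cy = center
    th = rng.uniform(0, 2 * np.pi, n)
    rad = R * np.sqrt(rng.uniform(0, 1, n))
    P = np.c_[cx + rad * np.cos(th), cy + rad * np.sin(th)]
    for scale in np.linspace(0.5, 1.0, 60):
        P, worst = _relax(P, scale * radii, R, center, gvc, gv_r,
                          sweeps=12, push=0.9, rng=rng,
                          jitter=0.25 * (1 - scale) + 0.02)
    for jit in (0.15, 0.08, 0.04, 0.02, 0.0):
        P, worst = _relax(P, radii, R, center, gvc, gv_r,
                          sweeps=150 if jit else 500, push=1.0, rng=rng, jitter=jit)
        if worst < 1e-3:
            break
    if worst > 0.05 * radii.min():
        raise PackingError(
            f"yolk packing failed to converge (residual overlap {worst:.2f} μm)")
    return P


def _dart_throw(rng, radii, R, center, gvc, gv_r, other_P, other_r,
                attempts=2000):
    """Sequential insertion of small granules into the gaps left by `other`.

    A granule that finds no admissible position within the attempt budget is
    provisionally placed at its least-overlapping candidate; the caller is
    expected to relax the configuration afterwards.  Returns (positions,
    radii, any_forced).
    """
    cx, cy = center
    tree = cKDTree(other_P) if len(other_P) else None
    reach = other_r.max() if len(other_r) else 0.0
    placed_P: List[np.ndarray] = []
    placed_r: List[float] = []
    forced = False
    for r0 in sorted(radii, reverse=True):
        best_p, best_excess = None, np.inf
        ok = False
        for _ in range(attempts):
            t = rng.uniform(0, 2 * np.pi)
            a = (R - r0) * np.sqrt(rng.uniform())
            p = np.array([cx + a * np.cos(t), cy + a * np.sin(t)])
            if np.hypot(p[0] - gvc[0], p[1] - gvc[1]) < gv_r + 0.9 * r0:
                continue
            worst = 0.0
            if tree is not None:
                idx = tree.query_ball_point(p, r0 + reach)
                if idx:
                    d = np.hypot(*(other_P[idx] - p).T)
                    lim = other_r[idx] + r0 \
                        - ALLOWED_OVERLAP * np.minimum(other_r[idx], r0)
                    worst = max(worst, float(np.max(lim - d, initial=0.0)))
            if placed_P:
                pp = np.asarray(placed_P)
                pr = np.asarray(placed_r)
                d = np.hypot(*(pp - p).T)
                lim = pr + r0 - ALLOWED_OVERLAP * np.minimum(pr, r0)
                worst = max(worst, float(np.max(lim - d, initial=0.0)))
            if worst <= 0:
                placed_P.append(p)
                placed_r.append(r0)
                ok = True
                break
            if worst < best_excess:
                best_excess, best_p = worst, p
        if not ok:
            if best_p is None:
                raise PackingError(
                    f"no admissible position for a granule of radius {r0:.1f} μm")
            placed_P.append(best_p)
            placed_r.append(r0)
            forced = True
    if not placed_P:
        return np.empty((0, 2)), np.empty(0), False
    return np.asarray(placed_P), np.asarray(placed_r), forced


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _make_asters(rng, params: SceneParams, override) -> pd.DataFrame:
    p = params
    cols = ["id", "x0", "y0", "t_on", "t_off", "sigma", "amplitude"]
    if override is not None:
        arr = np.asarray(override, dtype=float)
        if arr.size == 0:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame({
            "id": np.arange(len(arr)),
            "x0": arr[:, 0], "y0": arr[:, 1],
            "t_on": arr[:, 2], "t_off": arr[:, 3],
            "sigma": p.aster_sigma, "amplitude": p.aster_amplitude,
        })
    R = p.oocyte_radius
    area = np.pi * R * R
    peak = p.aster_density_peak * area / 1e5
    if peak < 0.5 or p.aster_wave_speed == 0:
        return pd.DataFrame(columns=cols)
    sweep_min = (np.pi * R) / p.aster_wave_speed        # AP->VP traversal, minutes
    life_min = p.aster_lifetime / 60.0
    n_total = int(np.ceil(peak * max(1.0, sweep_min / max(life_min, 1e-9))))
    cx, cy = p.center
    sep = 4.0 * p.aster_sigma
    pts: List[np.ndarray] = []
    for _ in range(n_total * 200):
        if len(pts) >= n_total:
            break
        t = rng.uniform(0, 2 * np.pi)
        a = (R - 2 * p.aster_sigma) * np.sqrt(rng.uniform())
        cand = np.array([cx + a * np.cos(t), cy + a * np.sin(t)])
        if pts and (np.hypot(*(np.asarray(pts) - cand).T) < sep).any():
            continue
        pts.append(cand)
    pts_arr = np.asarray(pts) if pts else np.empty((0, 2))
    dx, dy = pts_arr[:, 0] - cx, pts_arr[:, 1] - cy
    # angle from the animal pole (0 = AP), folded to [0, pi]; arc distance sets onset
    ang = np.abs(np.arctan2(dx, -dy))
    arc = ang * R
    t_on = p.gvbd_time + arc / p.aster_wave_speed * 60.0
    t_off = t_on + p.aster_lifetime * rng.uniform(0.8, 1.2, len(pts_arr))
    return pd.DataFrame({
        "id": np.arange(len(pts_arr)),
        "x0": pts_arr[:, 0], "y0": pts_arr[:, 1],
        "t_on": t_on, "t_off": t_off,
        "sigma": p.aster_sigma, "amplitude": p.aster_amplitude,
    })


def init_scene(params: SceneParams, *, yolk=None, cg=None, asters=None) -> SceneState:
    """Build the stage III scene at t = 0.

    ``yolk`` / ``cg`` may be (n, 3) arrays of explicit (x, y, radius) μm,
    bypassing the random packing (useful for constructed fixtures); ``asters``
    may be a (k, 4) array of (x, y, t_on, t_off).  With the default random
    placement, granules are packed inside the oocyte disk, outside the GV,
    with pairwise overlap depth at most 10% of the smaller radius; a
    :class:`PackingError` signals an infeasible density.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    R = p.oocyte_radius
    center = np.array(p.center)
    gvc = np.array([center[0], center[1] - (R - p.gv_radius)])

    if yolk is not None:
        yolk = np.asarray(yolk, dtype=float).reshape(-1, 3)
        yolk_P, yolk_r = yolk[:, :2], yolk[:, 2]
    elif p.n_yolk > 0:
        yolk_r = rng.uniform(*p.yolk_radius_range, p.n_yolk)
        yolk_P = _pack_yolk(rng, yolk_r, R, center, gvc, p.gv_radius)
    else:
        yolk_P, yolk_r = np.empty((0, 2)), np.empty(0)

    if cg is not None:
        cg = np.asarray(cg, dtype=float).reshape(-1, 3)
        cg_P, cg_r = cg[:, :2], cg[:, 2]
    elif p.n_cg > 0:
        cg_r = rng.uniform(*p.cg_radius_range, p.n_cg)
        cg_P, cg_r, forced = _dart_throw(rng, cg_r, R, center, gvc,
                                         p.gv_radius, yolk_P, yolk_r)
        if forced:
            # resolve the provisional placements with a short global relaxation
            all_P = np.vstack([yolk_P, cg_P]) if len(yolk_P) else cg_P
            all_r = np.concatenate([yolk_r, cg_r])
            for jit in (0.05, 0.0):
                all_P, worst = _relax(all_P, all_r, R, center, gvc,
                                      p.gv_radius, sweeps=120 if jit else 400,
                                      push=1.0, rng=rng, jitter=jit)
                if worst < 1e-3:
                    break
            if worst > 0.05 * all_r.min():
                raise PackingError(
                    f"granule density infeasible (residual overlap {worst:.2f} μm)")
            yolk_P = all_P[: len(yolk_r)]
            cg_P = all_P[len(yolk_r):]
    else:
        cg_P, cg_r = np.empty((0, 2)), np.empty(0)

    n_rab = p.n_rab11
    if n_rab > 0:
        th = rng.uniform(0, 2 * np.pi, n_rab)
        a = (R - 4.0) * np.sqrt(rng.uniform(0, 1, n_rab))
        rab_P = np.c_[center[0] + a * np.cos(th), center[1] + a * np.sin(th)]
        rab_r = np.full(n_rab, p.rab11_radius)
    else:
        rab_P, rab_r = np.empty((0, 2)), np.empty(0)

    n = len(yolk_r) + len(cg_r) + len(rab_r)
    ids = np.arange(n, dtype=np.int64)
    kind = np.array(["yolk"] * len(yolk_r) + ["cortical"] * len(cg_r)
                    + ["rab11"] * len(rab_r), dtype="U8")
    xs = np.concatenate([yolk_P[:, 0], cg_P[:, 0], rab_P[:, 0]])
    ys = np.concatenate([yolk_P[:, 1], cg_P[:, 1], rab_P[:, 1]])
    rs = np.concatenate([yolk_r, cg_r, rab_r])

    aster_df = _make_asters(rng, p, asters)

    if p.flow_profile_peak > 0 and p.n_pockets > 0:
        L = 2 * R
        # evenly spaced sampling stations along the AV axis, jittered
        base = 0.15 * L + 0.75 * L * (np.arange(p.n_pockets) + 0.5) / p.n_pockets
        s0 = base + rng.uniform(-3.0, 3.0, p.n_pockets)
        pockets = pd.DataFrame({
            "id": np.arange(p.n_pockets),
            "s0": s0,
            "lateral": rng.uniform(-4.0, 4.0, p.n_pockets),
            "speed": p.flow_profile_peak * (1.0 - s0 / L),
        })
    else:
        pockets = pd.DataFrame(columns=["id", "s0", "lateral", "speed"])

    target = int(round(len(yolk_r) * (1.0 - 2.0 ** (-p.fusion_rounds_mean))))
    return SceneState(
        params=p, time=0.0,
        ids=ids, kind=kind, x=xs, y=ys, r=rs,
        alive=np.ones(n, dtype=bool),
        death_time=np.full(n, np.nan),
        parents={}, asters=aster_df, pockets=pockets,
        next_id=n, fusion_log=[], fusions_done=0,
        target_fusions=target, rng=rng,
    )


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def step_scene(state: SceneState, dt: float) -> SceneState:
    """Advance the scene by ``dt`` seconds (all dynamics gated on GVBD).

    Yolk fusion conserves 3D volume exactly: the child radius is
    (r₁³ + r₂³)^(1/3) and it sits at the volume-weighted centroid of its
    parents.  Granules clamp at the cortex rather than exit.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    p = state.params
    s = state.copy()
    t0, t1 = s.time, s.time + dt
    s.time = t1
    dt_post = max(0.0, t1 - max(t0, p.gvbd_time))        # seconds after GVBD
    if dt_post <= 0:
        return s
    dmin = dt_post / 60.0
    cx, cy = p.center
    R = p.oocyte_radius

    # -- advection ---------------------------------------------------------
    yi = s.alive_of("yolk")
    if len(yi) and p.compaction_speed > 0:
        dx, dy = s.x[yi] - cx, s.y[yi] - cy
        d = np.hypot(dx, dy)
        nz = d > 1e-9
        dn = np.maximum(0.0, d - p.compaction_speed * dmin)
        scale = np.where(nz, dn / np.maximum(d, 1e-9), 0.0)
        s.x[yi] = cx + dx * scale
        s.y[yi] = cy + dy * scale
    ci = s.alive_of("cortical")
    if len(ci) and p.cg_outward_speed > 0:
        dx, dy = s.x[ci] - cx, s.y[ci] - cy
        d = np.hypot(dx, dy)
        u_x = np.where(d > 1e-9, dx / np.maximum(d, 1e-9), 0.0)
        u_y = np.where(d > 1e-9, dy / np.maximum(d, 1e-9), -1.0)
        dn = np.minimum(R - s.r[ci], d + p.cg_outward_speed * dmin)
        s.x[ci] = cx + u_x * dn
        s.y[ci] = cy + u_y * dn
    ri = s.alive_of("rab11")
    if len(ri) and p.rab11_outward_speed > 0:
        dx, dy = s.x[ri] - cx, s.y[ri] - cy
        d = np.hypot(dx, dy)
        u_x = np.where(d > 1e-9, dx / np.maximum(d, 1e-9), 0.0)
        u_y = np.where(d > 1e-9, dy / np.maximum(d, 1e-9), -1.0)
        dn = np.minimum(R - 2.0, d + p.rab11_outward_speed * dmin)
        s.x[ri] = cx + u_x * dn
        s.y[ri] = cy + u_y * dn

    # -- yolk fusion -------------------------------------------------------
    f_rem = s.target_fusions - s.fusions_done
    yi = s.alive_of("yolk")
    if f_rem > 0 and len(yi) >= 2:
        t_end = max(p.total_duration, t0 + dt)
        steps_rem = max(1, int(np.ceil((t_end - t0) / dt)))
        P = np.c_[s.x[yi], s.y[yi]]
        tree = cKDTree(P)
        pairs = tree.query_pairs(2 * s.r[yi].max(), output_type="ndarray")
        if len(pairs):
            a, b = pairs[:, 0], pairs[:, 1]
            dist = np.hypot(s.x[yi][a] - s.x[yi][b], s.y[yi][a] - s.y[yi][b])
            contact = dist < s.r[yi][a] + s.r[yi][b]
            pairs = pairs[contact]
        if len(pairs):
            prob = min(1.0, f_rem / (len(pairs) * steps_rem))
            gid = s.ids[yi]
            order = np.lexsort((np.maximum(gid[pairs[:, 0]], gid[pairs[:, 1]]),
                                np.minimum(gid[pairs[:, 0]], gid[pairs[:, 1]])))
            consumed: set = set()
            draws = s.rng.random(len(pairs))
            for k in order:
                if s.fusions_done >= s.target_fusions:
                    break
                ia, ib = yi[pairs[k, 0]], yi[pairs[k, 1]]
                if ia in consumed or ib in consumed:
                    continue
                if draws[k] >= prob:
                    continue
                consumed.update((ia, ib))
                v1, v2 = s.r[ia] ** 3, s.r[ib] ** 3
                child_r = (v1 + v2) ** (1.0 / 3.0)
                child_x = (v1 * s.x[ia] + v2 * s.x[ib]) / (v1 + v2)
                child_y = (v1 * s.y[ia] + v2 * s.y[ib]) / (v1 + v2)
                s.alive[ia] = s.alive[ib] = False
                cid = s.next_id
                s.next_id += 1
                s.ids = np.append(s.ids, cid)
                s.kind = np.append(s.kind, "yolk")
                s.x = np.append(s.x, child_x)
                s.y = np.append(s.y, child_y)
                s.r = np.append(s.r, child_r)
                s.alive = np.append(s.alive, True)
                s.death_time = np.append(s.death_time, np.nan)
                s.parents[cid] = (int(s.ids[ia]), int(s.ids[ib]))
                s.fusion_log.append({
                    "time": t1, "parent1": int(s.ids[ia]),
                    "parent2": int(s.ids[ib]), "child": cid,
                })
                s.fusions_done += 1

    # -- K+ vesicles -------------------------------------------------------
    lo = max(t0, p.gvbd_time)
    hi = min(t1, p.gvbd_time + p.kplus_window)
    dt_k = max(0.0, hi - lo)
    if dt_k > 0 and p.kplus_rate > 0:
        n_new = s.rng.poisson(p.kplus_rate * dt_k / 60.0)
        existing = s.alive_of("kplus")
        for _ in range(n_new):
            for _attempt in range(200):
                th = s.rng.uniform(0, 2 * np.pi)
                a = (R - 4.0 * p.kplus_radius) * np.sqrt(s.rng.uniform())
                px_, py_ = cx + a * np.cos(th), cy + a * np.sin(th)
                ki = s.alive_of("kplus")
                if len(ki):
                    d = np.hypot(s.x[ki] - px_, s.y[ki] - py_)
                    if (d < 4.0 * p.kplus_radius).any():
                        continue
                break
            nid = s.next_id
            s.next_id += 1
            s.ids = np.append(s.ids, nid)
            s.kind = np.append(s.kind, "kplus")
            s.x = np.append(s.x, px_)
            s.y = np.append(s.y, py_)
            s.r = np.append(s.r, p.kplus_radius)
            s.alive = np.append(s.alive, True)
            s.death_time = np.append(
                s.death_time, t1 + p.kplus_lifetime * s.rng.uniform(0.7, 1.3))
    ki = s.alive_of("kplus")
    dead = ki[np.nan_to_num(s.death_time[ki], nan=np.inf) <= t1]
    s.alive[dead] = False

    # -- Cg exocytosis on activation ----------------------------------------
    if p.activation_time is not None and t0 < p.activation_time <= t1:
        ci = s.alive_of("cortical")
        gone = s.rng.random(len(ci)) < p.cg_exocytosis_frac
        s.alive[ci[gone]] = False

    return s


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _paint_disks(img, xs, ys, rs, value, pixel_size):
    """Set pixels whose center lies within a disk to ``value`` (overwrite)."""
    n = img.shape[0]
    for gx, gy, gr in zip(xs, ys, rs):
        j0 = max(0, int((gx - gr) / pixel_size) - 1)
        j1 = min(n, int((gx + gr) / pixel_size) + 2)
        i0 = max(0, int((gy - gr) / pixel_size) - 1)
        i1 = min(n, int((gy + gr) / pixel_size) + 2)
        if j1 <= j0 or i1 <= i0:
            continue
        jj = (np.arange(j0, j1) + 0.5) * pixel_size - gx
        ii = (np.arange(i0, i1) + 0.5) * pixel_size - gy
        m = ii[:, None] ** 2 + jj[None, :] ** 2 <= gr * gr
        img[i0:i1, j0:j1][m] = value


def _paint_gaussians(img, xs, ys, sigmas, amps, pixel_size):
    n = img.shape[0]
    for gx, gy, sg, am in zip(xs, ys, sigmas, amps):
        ext = 4.0 * sg
        j0 = max(0, int((gx - ext) / pixel_size) - 1)
        j1 = min(n, int((gx + ext) / pixel_size) + 2)
        i0 = max(0, int((gy - ext) / pixel_size) - 1)
        i1 = min(n, int((gy + ext) / pixel_size) + 2)
        if j1 <= j0 or i1 <= i0:
            continue
        jj = (np.arange(j0, j1) + 0.5) * pixel_size - gx
        ii = (np.arange(i0, i1) + 0.5) * pixel_size - gy
        d2 = ii[:, None] ** 2 + jj[None, :] ** 2
        img[i0:i1, j0:j1] += am * np.exp(-d2 / (2 * sg * sg))


# nominal fluorophore levels per channel (arbitrary intensity units)
_LV = {
    "exterior": 0.02,
    "ooplasm": {"interior": 1.0, "granule": 0.1, "gv": 0.2, "pocket": 0.55},
    "lysotracker": {"interior": 0.25, "yolk": 1.0, "cortical": 0.05},
    "microtubule": {"interior": 0.35},
    "rab11": {"interior": 0.08, "punctum": 1.0},
    "kplus": {"interior": 0.05, "vesicle": 1.0},
    "brightfield": {"base": 1.0, "yolk_attenuation": 0.55},
}


def apply_noise(img, rng, photon_scale, read_sigma):
    """Poisson photon noise at the given rate plus additive Gaussian read noise."""
    out = img
    if photon_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * photon_scale) / photon_scale
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, out.shape)
    return out.astype(np.float32)


def render_frame(state: SceneState, params: Optional[SceneParams] = None) -> np.ndarray:
    """Render the multichannel (C, Y, X) float image of the current state.

    Channel semantics: ooplasm — interior bright with all granules dark;
    lysotracker — Yg bright, Cg darker than the ooplasm background;
    microtubule — uniform network plus Gaussian aster spots; rab11/kplus —
    small bright puncta; brightfield — attenuation proportional to local
    Yg coverage.  A Gaussian PSF blur and the photon/read noise model are
    applied last; the rendering noise stream is derived from (seed, frame
    index) so re-rendering the same state is bit-identical.
    """
    p = params or state.params
    n = p.image_px
    if n < 8:
        raise RenderError(
            f"pixel_size {p.pixel_size} leaves only {n} px across the field of view")
    px = p.pixel_size
    cx, cy = p.center
    R = p.oocyte_radius

    yy, xx = np.mgrid[0:n, 0:n]
    xum = (xx + 0.5) * px
    yum = (yy + 0.5) * px
    interior = (xum - cx) ** 2 + (yum - cy) ** 2 <= R * R

    yi = state.alive_of("yolk")
    ci = state.alive_of("cortical")
    ki = state.alive_of("kplus")
    ri = state.alive_of("rab11")
    lv = _LV

    chans = {}

    img = np.full((n, n), lv["exterior"], dtype=np.float64)
    img[interior] = lv["ooplasm"]["interior"]
    pk = state.pocket_positions()
    if len(pk):
        _paint_disks(img, pk.x.values, pk.y.values, np.full(len(pk), 4.0),
                     lv["ooplasm"]["pocket"], px)
    for idx in (yi, ci, ki):
        _paint_disks(img, state.x[idx], state.y[idx], state.r[idx],
                     lv["ooplasm"]["granule"], px)
    gv_fade = 1.0
    if state.time > p.gvbd_time:
        gv_fade = max(0.0, 1.0 - (state.time - p.gvbd_time) / 300.0)
    if gv_fade > 0:
        gvc = (cx, cy - (R - p.gv_radius))
        gv_val = (gv_fade * lv["ooplasm"]["gv"]
                  + (1 - gv_fade) * lv["ooplasm"]["interior"])
        _paint_disks(img, [gvc[0]], [gvc[1]], [p.gv_radius], gv_val, px)
    chans["ooplasm"] = img

    img = np.full((n, n), lv["exterior"], dtype=np.float64)
    img[interior] = lv["lysotracker"]["interior"]
    _paint_disks(img, state.x[ci], state.y[ci], state.r[ci],
                 lv["lysotracker"]["cortical"], px)
    _paint_disks(img, state.x[yi], state.y[yi], state.r[yi],
                 lv["lysotracker"]["yolk"], px)
    chans["lysotracker"] = img
    yolk_mask = img >= lv["lysotracker"]["yolk"]   # reused for brightfield

    img = np.full((n, n), lv["exterior"], dtype=np.float64)
    img[interior] = lv["microtubule"]["interior"]
    ast = state.active_asters()
    if len(ast):
        _paint_gaussians(img, ast.x.values, ast.y.values,
                         ast.sigma.values, ast.amplitude.values, px)
    chans["microtubule"] = img

    img = np.full((n, n), lv["exterior"], dtype=np.float64)
    img[interior] = lv["rab11"]["interior"]
    _paint_disks(img, state.x[ri], state.y[ri], state.r[ri],
                 lv["rab11"]["punctum"], px)
    chans["rab11"] = img

    img = np.full((n, n), lv["exterior"], dtype=np.float64)
    img[interior] = lv["kplus"]["interior"]
    _paint_disks(img, state.x[ki], state.y[ki], state.r[ki],
                 lv["kplus"]["vesicle"], px)
    chans["kplus"] = img

    img = np.full((n, n), lv["brightfield"]["base"], dtype=np.float64)
    img[yolk_mask] -= lv["brightfield"]["yolk_attenuation"]
    chans["brightfield"] = img

    stack = np.stack([chans[c] for c in CHANNELS])
    if p.psf_sigma > 0:
        sig = p.psf_sigma / px
        for c in range(stack.shape[0]):
            stack[c] = gaussian_filter(stack[c], sig)
    frame_idx = int(round(state.time / p.frame_interval))
    rng = np.random.default_rng((p.seed, 10007, frame_idx))
    out = np.empty_like(stack, dtype=np.float32)
    for c in range(stack.shape[0]):
        out[c] = apply_noise(stack[c], rng, p.photon_scale, p.read_noise_sigma)
    return out


# ---------------------------------------------------------------------------
# end-to-end drivers
# ---------------------------------------------------------------------------

def _true_velocities(p: SceneParams) -> pd.DataFrame:
    rows = [
        ("yolk_compaction", -p.compaction_speed),
        ("cg_outward", p.cg_outward_speed),
        ("aster_drift", p.aster_drift_speed),
        ("aster_wave", p.aster_wave_speed),
        ("rab11_outward", p.rab11_outward_speed),
    ]
    if p.flow_profile_peak > 0:
        rows.append(("ooplasm_flow_peak", p.flow_profile_peak))
    return pd.DataFrame(rows, columns=["process", "speed_um_per_min"])


def generate_timelapse(params: SceneParams, *, yolk=None, cg=None, asters=None,
                       return_states=False):
    """Simulate and render the full maturation run.

    Returns (TimeLapse, GroundTruth); frames are quantized to uint16.  Pass
    ``return_states=True`` to additionally receive the per-frame SceneStates
    (handy for noiseless re-rendering in tests).
    """
    p = params
    state = init_scene(p, yolk=yolk, cg=cg, asters=asters)
    frames = []
    states = []
    gran_rows = []
    aster_rows = []
    fusion_rows = []
    n_logged = 0
    for f in range(p.n_frames):
        if f > 0:
            state = step_scene(state, p.frame_interval)
        states.append(state)
        live = np.flatnonzero(state.alive)
        for i in live:
            gran_rows.append((f, int(state.ids[i]), str(state.kind[i]),
                              float(state.x[i]), float(state.y[i]), float(state.r[i])))
        ast = state.active_asters()
        for _, row in ast.iterrows():
            aster_rows.append((f, int(row.id), float(row.x), float(row.y)))
        for ev in state.fusion_log[n_logged:]:
            fusion_rows.append((f, ev["parent1"], ev["parent2"], ev["child"]))
        n_logged = len(state.fusion_log)
        img = render_frame(state, p)
        frames.append(np.clip(img * UINT16_GAIN, 0, 65535).astype(np.uint16))

    tl = TimeLapse(
        frames=np.stack(frames),
        channel_names=list(CHANNELS),
        pixel_size=p.pixel_size,
        frame_interval=p.frame_interval,
        axis_annotation=0.0,
    )
    gt = GroundTruth(
        granule_tracks=pd.DataFrame(
            gran_rows, columns=["frame", "id", "kind", "x", "y", "radius"]),
        fusion_events=pd.DataFrame(
            fusion_rows, columns=["frame", "parent1", "parent2", "child"]),
        aster_tracks=pd.DataFrame(aster_rows, columns=["frame", "id", "x", "y"]),
        true_velocities=_true_velocities(p),
        meta={"mode": "maturation"},
    )
    if return_states:
        return tl, gt, states
    return tl, gt


# ---------------------------------------------------------------------------
# voxel scene for the volume pipeline
# ---------------------------------------------------------------------------

def make_voxel_stacks(params: SceneParams, voxel_xy: float = 2.0,
                      z_step: float = 2.0) -> Tuple[np.ndarray, np.ndarray]:
    """Binary z-stacks (Z, Y, X) of the oocyte sphere and the GV sphere.

    The GV is placed tangent to the animal pole, fully inside the oocyte;
    slice planes sit at z = (k + 0.5) * z_step.  Used by the voxel-count
    volume measurement.
    """
    R = params.oocyte_radius
    rg = params.gv_radius
    n_xy = int(np.ceil(2 * R / voxel_xy))
    n_z = int(np.ceil(2 * R / z_step))
    c = n_xy * voxel_xy / 2.0
    yy, xx = np.mgrid[0:n_xy, 0:n_xy]
    d2 = ((xx + 0.5) * voxel_xy - c) ** 2 + ((yy + 0.5) * voxel_xy - c) ** 2
    oocyte = np.zeros((n_z, n_xy, n_xy), dtype=np.uint8)
    gv = np.zeros_like(oocyte)
    # GV center: on the z axis of the stack at depth rg (tangent to the top)
    for k in range(n_z):
        z = (k + 0.5) * z_step
        h2 = R * R - (z - R) ** 2
        if h2 > 0:
            oocyte[k] = d2 <= h2
        g2 = rg * rg - (z - rg) ** 2
        if g2 > 0:
            gv[k] = d2 <= g2
    return oocyte, gv
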