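"""Parameterization of the synthetic oocyte-maturation scene.

The defaults describe a stage III zebrafish oocyte: a ~600 μm cell with a
germinal vesicle (GV) at the animal pole occupying ~1.5% of the cell volume,
densely packed with large Lysotracker-positive yolk granules (Yg) and small
cortical granules (Cg) that are dark in both the ooplasm and Lysotracker
channels.  After GV breakdown (GVBD) the scene plays out the maturation
kinematics: Yg fuse pairwise (3D volume conserved) and advect toward the
oocyte center, Cg advect outward, K⁺-filled vesicles appear and later fuse
away, microtubule asters form in an animal-to-vegetal wave and drift toward
the cortex, and Rab11 puncta co-translocate outward.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import yaml

#: Channel order of every rendered frame.
CHANNELS = ("ooplasm", "lysotracker", "microtubule", "rab11", "kplus", "brightfield")

#: Margin of the field of view around the oocyte (fraction of its diameter).
FOV_MARGIN = 1.04

#: Gain applied when quantizing rendered float intensities to uint16.
UINT16_GAIN = 10000.0


@dataclass(frozen=True)
class SceneParams:
    """All knobs of the synthetic scene.  Lengths in μm, times in s, speeds in μm/min."""

    oocyte_diameter: float = 600.0
    gv_diameter: float = 148.0          # (148/600)^3 ≈ 1.5% of the oocyte volume
    pixel_size: float = 1.0             # μm per pixel
    frame_interval: float = 60.0        # s per frame
    n_frames: int = 60
    n_yolk: int = 300
    n_cg: int = 600
    yolk_radius_range: Tuple[float, float] = (8.0, 20.0)
    cg_radius_range: Tuple[float, float] = (2.0, 5.0)
    fusion_rounds_mean: float = 1.5     # expected pairwise-fusion rounds per Yg over the run
    gvbd_time: float = 300.0            # s; dynamics are gated on GV breakdown
    compaction_speed: float = 0.3       # Yg inward, μm/min
    cg_outward_speed: float = 0.3       # μm/min
    aster_wave_speed: float = 30.0      # μm/min along the circumference, AP -> VP
    aster_drift_speed: float = 0.5      # μm/min radially outward
    aster_density_peak: float = 15.0    # peak count per 10^5 μm^2
    aster_sigma: float = 6.0            # μm, Gaussian aster footprint
    aster_lifetime: float = 1200.0      # s from formation to dissolution
    aster_amplitude: float = 0.8        # intensity above the microtubule background
    n_rab11: int = 150
    rab11_radius: float = 1.5
    rab11_outward_speed: float = 0.5
    kplus_rate: float = 1.5             # vesicle appearances per minute after GVBD
    kplus_window: float = 1500.0        # s during which K+ vesicles keep appearing
    kplus_lifetime: float = 900.0       # s until a K+ vesicle fuses away
    kplus_radius: float = 2.0
    flow_profile_peak: float = 0.0      # ooplasm-pocket speed at the AP, μm/min; 0 = off
    n_pockets: int = 12
    activation_time: Optional[float] = None   # s; triggers Cg exocytosis
    cg_exocytosis_frac: float = 0.6
    photon_scale: float = 200.0         # expected photons at unit intensity; 0 = noiseless
    read_noise_sigma: float = 0.01      # additive Gaussian read noise (intensity units)
    psf_sigma: float = 1.0              # μm; 0 = no blur
    field_size: float = 200.0           # side of the square contraction-series patch
    contraction_speed: float = 3.0      # μm/min of network speckles toward attractors
    network_coverage: float = 0.3       # area fraction of the initial filament network
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        p = self
        positive = {
            "oocyte_diameter": p.oocyte_diameter,
            "gv_diameter": p.gv_diameter,
            "pixel_size": p.pixel_size,
            "frame_interval": p.frame_interval,
            "field_size": p.field_size,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        nonneg = {
            "n_frames": p.n_frames,
            "n_yolk": p.n_yolk,
            "n_cg": p.n_cg,
            "fusion_rounds_mean": p.fusion_rounds_mean,
            "gvbd_time": p.gvbd_time,
            "compaction_speed": p.compaction_speed,
            "cg_outward_speed": p.cg_outward_speed,
            "aster_wave_speed": p.aster_wave_speed,
            "aster_drift_speed": p.aster_drift_speed,
            "aster_density_peak": p.aster_density_peak,
            "kplus_rate": p.kplus_rate,
            "photon_scale": p.photon_scale,
            "read_noise_sigma": p.read_noise_sigma,
            "psf_sigma": p.psf_sigma,
            "flow_profile_peak": p.flow_profile_peak,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if p.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not p.gv_diameter < p.oocyte_diameter:
            raise ValueError("gv_diameter must be smaller than oocyte_diameter")
        for name, rng in (("yolk_radius_range", p.yolk_radius_range),
                          ("cg_radius_range", p.cg_radius_range)):
            lo, hi = rng
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be ordered and positive, got {rng!r}")
        if not 0 < p.network_coverage < 1:
            raise ValueError("network_coverage must be in (0, 1)")

    # -- derived geometry ---------------------------------------------------

    @property
    def image_px(self) -> int:
        """Side of the rendered square frame, in pixels."""
        return int(round(self.oocyte_diameter * FOV_MARGIN / self.pixel_size))

    @property
    def oocyte_radius(self) -> float:
        return self.oocyte_diameter / 2.0

    @property
    def gv_radius(self) -> float:
        return self.gv_diameter / 2.0

    @property
    def center(self) -> Tuple[float, float]:
        """Oocyte center in μm (x, y); origin at the image top-left corner."""
        half = self.image_px * self.pixel_size / 2.0
        return (half, half)

    @property
    def total_duration(self) -> float:
        """Time spanned by the run in seconds (first to last frame)."""
        return (self.n_frames - 1) * self.frame_interval

    # -- (de)serialization --------------------------------------------------

    def replace(self, **changes) -> "SceneParams":
        return dataclasses.replace(self, **changes)

    def noiseless(self) -> "SceneParams":
        """Copy with photon/read noise and PSF blur switched off."""
        return self.replace(photon_scale=0.0, read_noise_sigma=0.0, psf_sigma=0.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["yolk_radius_range"] = list(d["yolk_radius_range"])
        d["cg_radius_range"] = list(d["cg_radius_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        d = dict(d)
        for key in ("yolk_radius_range", "cg_radius_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SceneParams":
        """Load parameters from a JSON or YAML config file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))
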