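# oomat

Quantitative image analysis of **zebrafish oocyte maturation** from
multi-channel fluorescence time-lapses — with a synthetic-scene generator
that makes every measurement testable against known ground truth.

During maturation, germinal-vesicle breakdown (GVBD) sets off a cascade of
cytoplasmic reorganizations: yolk granules (Yg) fuse pairwise — roughly
doubling their mean cross-sectional area — and compact toward the oocyte
center; cortical granules (Cg) are carried outward to the cortex;
the microtubule network collapses into acentrosomal asters in an
animal-to-vegetal wave, the asters drifting outward together with
Rab11-positive vesicles; K⁺-filled vesicles appear and fuse away; and upon
egg activation the Cg are exocytosed, elevating the chorion.  `oomat`
implements the image-quantification side of this biology for researchers
analyzing such time-lapses (or building comparable pipelines):

* **`oomat.scene` / `oomat.contraction`** — seeded synthetic oocyte and
  contraction-patch time-lapses (multi-channel TIFF + ground-truth tables):
  volume-conserving pairwise fusion (r_child = (r₁³+r₂³)^⅓), prescribed
  advection, an aster-formation wave, photon + read noise, PSF blur.
* **`oomat.segment` / `oomat.track`** — classical threshold + watershed
  segmentation of the oocyte, Yg, Cg, K⁺ vesicles and Rab11 puncta, and
  overlap-based tracking that records merge (fusion) events.
* **`oomat.radial`** — oocyte geometry R(θ) at 5° increments, per-angle
  normalized-radius phase-fraction profiles, Cg radial histograms and
  surface densities, ROI intensity series, voxel-count volumes.
* **`oomat.kymo`** — width-averaged kymographs along lines or
  circumferential arcs; edge (half-max) and ridge (robust Siegel fit)
  velocimetry; flow profiles; wave-front speeds.
* **`oomat.asters`** — Laplacian-of-Gaussian aster detection and counting,
  temporal max-projections, and the Voronoi contraction-domain analysis
  with the percolation-style ξ1/ξ2 readout (ξ1 ≈ ξ2: local contraction;
  ξ1 near the system size: large-scale contraction).
* **`oomat.events`** — fusion-event histograms, mean-area series,
  Cg depletion ratios, K⁺-vesicle counts, chorion-elevation ratios.

A thin `oomat` command-line interface wraps these
(`oomat simulate | segment | track | phases | density | roi | volume |
kymo | asters | contraction | events | depletion | chorion`).

## Worked example

Simulate a sparse maturation run, segment and track the yolk granules, and
recover the fusion events and mean-area growth:

```python
import numpy as np
import oomat
from oomat.segment import segment_granules, segment_oocyte
from oomat.track import track_labels
from oomat.events import fusion_histogram, mean_area_series

params = oomat.SceneParams(oocyte_diameter=240, gv_diameter=59.2, n_yolk=20,
                           n_cg=0, n_rab11=0, kplus_rate=0.0,
                           aster_density_peak=0.0, n_frames=25,
                           gvbd_time=120.0, fusion_rounds_mean=1.0, seed=11)
tl, truth = oomat.generate_timelapse(params)

mask = segment_oocyte(np.maximum(tl.frames[0, 0], tl.frames[0, 1]).astype(float))
labels = [segment_granules({n: tl.frames[f, i].astype(float)
                            for i, n in enumerate(tl.channel_names)},
                           "yolk", tl.pixel_size, mask, frame_index=f)
          for f in range(params.n_frames)]
tracks = track_labels(labels)

series, factor = mean_area_series(tracks)
counts, _ = fusion_histogram(tracks, bin_minutes=5.0,
                             frame_interval_s=params.frame_interval)
yg = truth.granule_tracks[truth.granule_tracks.kind == "yolk"]
true_factor = ((yg[yg.frame == 24].radius ** 2).mean()
               / (yg[yg.frame == 0].radius ** 2).mean())
print(f"fusion events detected: {counts.sum()} (ground truth: {len(truth.fusion_events)})")
print(f"mean Yg area: {series.iloc[0]:.0f} -> {series.iloc[-1]:.0f} um^2")
print(f"area factor: {factor:.3f} measured vs {true_factor:.3f} ground truth")
```

prints

```
fusion events detected: 8 (ground truth: 8)
mean Yg area: 624 -> 802 um^2
area factor: 1.286 measured vs 1.290 ground truth
```

Every one of the 8 volume-conserving fusions scripted by the generator is
recovered as a tracking merge, and the measured mean-area growth matches
the ground-truth tables to within half a percent.  (At the full default
scene — 300 yolk granules and 1.5 expected fusion rounds per granule — the
same pipeline recovers the characteristic mean-area **doubling**.)

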