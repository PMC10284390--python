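# Methods

`oomat` quantifies cytoplasmic reorganization in maturing zebrafish oocytes
from multi-channel fluorescence time-lapses, and ships a synthetic-scene
generator that emulates the imaged biology closely enough that every
analysis stage can be validated against known ground truth.  This note
documents the model behind the generator, the measurement procedures, the
numerical choices, and what passing tests do and do not demonstrate.

## The synthetic scene

### Geometry and channels

A stage III oocyte is modeled as a disk of diameter 600 μm (the biological
range is roughly 500–690 μm) with the germinal vesicle (GV) as a disk of
diameter 148 μm placed tangent to the animal pole.  That GV diameter is
chosen so that, as spheres, GV/oocyte volume = (148/600)³ ≈ 1.5%, the
fraction the GV occupies in a stage III oocyte.  Coordinates are in μm with
the origin at the image top-left corner, x rightward and y downward; pixel
(i, j) has its center at ((j+0.5)·px, (i+0.5)·px); angle 0 points at the
animal pole and increases clockwise.

Six channels are rendered per frame, each as flat nominal fluorophore
levels before blur and noise:

| channel      | semantics                                                       |
|--------------|-----------------------------------------------------------------|
| ooplasm      | cytoplasm bright; all granules and the GV dark                  |
| lysotracker  | yolk granules (Yg) bright; cortical granules (Cg) darker than the ooplasmic background |
| microtubule  | uniform network plus Gaussian aster spots (σ = 6 μm)            |
| rab11        | small bright puncta (r = 1.5 μm)                                |
| kplus        | K⁺-indicator vesicles as bright disks (r = 2 μm)                |
| brightfield  | transmitted-light proxy: attenuation proportional to local Yg coverage |

A Gaussian PSF (σ = 1 μm by default) is applied, then Poisson photon noise
(200 expected photons at unit intensity) and additive Gaussian read noise
(σ = 0.01).  Frames are quantized to uint16 at a fixed gain.  The rendering
noise stream is keyed on (seed, frame index), so a given state renders
bit-identically.

### Granule packing

The defaults — 300 Yg with radii uniform in 8–20 μm and 600 Cg with radii
2–5 μm — put the nominal packed area at ~80% of the available cross
section, close to random close packing for a polydisperse disk system.
Plain rejection sampling cannot reach that density, so packing is
hierarchical: yolk granules are placed by a growth-and-relaxation protocol
(radii inflated along a schedule while overlapping pairs are pushed apart,
with a small annealing jitter), and cortical granules are then dart-thrown
into the interstitial gaps.  Pairwise overlap depth is bounded by 10% of the
smaller radius.  If a cortical granule finds no admissible spot within the
attempt budget, it is placed at its least-overlapping candidate and a short
global relaxation resolves the residuals; a configuration that still
violates the overlap bound raises `PackingError`.  The result is
deterministic given (parameters, seed).

### Dynamics

All dynamics are gated on GV breakdown (GVBD, default t = 300 s) and are
**prescribed kinematics**, not a hydrodynamic model — the artifact measures
motion, it does not explain it:

* **Yolk fusion.**  Contacting Yg pairs fuse with a per-pair per-step
  probability.  Fusion conserves 3D volume exactly: the child radius is
  (r₁³ + r₂³)^(1/3) and the child sits at the volume-weighted centroid.
  The probability is calibrated adaptively as
  F_remaining / (n_contact_pairs × steps_remaining), where the run target is
  F\* = n_yolk·(1 − 2^(−m)) and m = `fusion_rounds_mean` (default 1.5).
  Halving the population per "round" multiplies the mean cross-sectional
  area by 2^(2/3) per round, so m = 1.5 targets a mean-area factor of
  2^(2·1.5/3) = 2 — the doubling observed in maturing oocytes.  Simulated
  runs land at ≈1.89–1.94 (contact-weighted pairing in a polydisperse
  population runs a few percent below the monodisperse closed form), inside
  the 10% acceptance band.  Pairs are processed in ascending (min id) order;
  ties are therefore deterministic.
* **Advection.**  Yg advect toward the oocyte center at 0.3 μm/min and
  Cg outward at 0.3 μm/min, clamping at the center/cortex.  The
  volume-weighted mean Yg distance to center is provably non-increasing
  per step (the number-weighted mean can fluctuate transiently when two
  near-center granules fuse, and is only tested for a net decrease).
* **Microtubule asters.**  Aster sites (min separation 4σ) switch on when
  an animal-to-vegetal circumferential wave (default 30 μm/min) reaches
  their angular coordinate, live ~20 min, and drift radially outward at
  0.5 μm/min — producing the characteristic rise-then-fall of the aster
  count.  Amplitude is constant while alive so that zero-noise detection
  counts are exactly the ground-truth counts.
* **K⁺ vesicles** appear after GVBD (default 1.5/min for 25 min, ≥8 μm
  apart, clear of the cortex) and disappear after a ~15 min lifetime,
  emulating their fusion into Yg.
* **Rab11 puncta** drift outward at 0.5 μm/min.
* **Ooplasm pockets** (off by default) activate a blastodisc-flow mode:
  dark tracer pockets at evenly spaced stations along the AV axis move
  toward the animal pole at v(s) = v₀·(1 − s/L), giving a flow profile
  maximal at the AP and decaying toward the VP.
* **Activation** (off by default) removes each Cg with a configurable
  probability at `activation_time`, emulating exocytosis.

Every run emits a `GroundTruth` record — granule tracks, fusion events,
aster tracks, true speeds, and (for contraction series) the domain map —
used as the oracle in tests.

### Contraction series

A speckled filament network (thresholded smoothed noise, 30% coverage) on a
200 μm square patch contracts at 3 μm/min toward one attractor (global
mode) or an n-focus grid (local mode); particles stop 0–3 μm short so the
final clusters are compact blobs.  Because each speckle travels on a
straight line to its attractor, the true contraction domain of a pixel is
exactly its nearest-attractor basin, recorded as the ground-truth
`domain_map`.  Full collapse requires speed × duration ≥ L/√2; the defaults
(60 frames × 60 s) satisfy this.

### Voxel scene

`make_voxel_stacks` digitizes the oocyte and GV spheres at 2 μm voxels for
the voxel-count volume measurement; the recovered GV/oocyte volume fraction
is 1.503% against the analytic 1.5%.

## Measurements

* **Oocyte mask** — smooth (σ = 3 px), threshold halfway between the border
  background and the 99.5th percentile, keep the largest component, close
  (disk r = 10 px) and fill, then take the convex hull.  The background-
  referenced threshold is used instead of Otsu because the granule-textured
  interior is multi-modal; the closing and hull seal boundary notches cut
  by dark structures abutting the rim — notably the GV, whose tangent
  contact makes its notch topologically unfillable.  The hull is exact for
  the convex oocyte cross-section and can be disabled for non-convex
  objects.
* **Granule segmentation** — Gaussian smoothing (σ = 1 px), a global
  threshold (Otsu within the mask by default, overridable), a
  distance-transform watershed to split touching granules (marker
  separation 6 μm for yolk, 2 μm for the small classes), and a minimum-area
  filter (yolk 20 μm², cortical 3 μm², K⁺ 6 μm², Rab11 4 μm²).  Cortical
  granules are the pixels dark in both the ooplasm and Lysotracker channels
  inside the mask eroded by 2 μm; their Lysotracker cutoff is anchored
  between the darkest percentile and the background median because plain
  Otsu is dragged upward by bright boundary smear.  Bright-puncta channels
  carry two guards — class separation must exceed 10× the pixel-noise scale,
  and puncta must be sparse (<35% of the mask) — so a signal-free channel
  yields zero objects rather than thresholded noise.  The 2 μm rim
  exclusion reproduces the known segmentation artifact of undercounting Cg
  immediately at the cortex.
* **Tracking** — frame-to-frame linking by maximal pixel overlap (ties:
  larger overlap, then smaller track id); a label receiving two or more
  links is recorded as a merge, the largest-overlap track surviving.
  Overlap linking is appropriate because granules move ≲0.5 px per frame.
* **Radial profiles** — the oocyte boundary radius is measured on 72 rays
  at 5° increments; each pixel's normalized radius uses its own angle's
  R(θ) (periodic linear interpolation).  Phase fractions are normalized to
  the sum of the phases per bin (20 bins on [0, 1] by default); unoccupied
  bins are masked as NaN, never reported as 0.  The Cg histogram uses the
  conventional 0.05 bin width; surface density is granule area over the
  plane (oocyte cross-section) area.
* **Kymographs** — bilinear sampling along a line or circumferential arc,
  averaged across the band width; rows are spaced at the pixel size.
  Edge velocimetry localizes the half-max crossing per column (tracking
  continuity across columns) and fits least squares; ridge velocimetry
  takes the per-column intensity maximum with parabolic sub-pixel
  refinement and fits a robust repeated-median (Siegel) line.  Speeds are
  reported in μm/min, positive toward increasing position, with R² as fit
  quality.  The wave speed is the inverse slope of onset time vs arc
  position; simultaneous onset returns `inf` as a documented sentinel.
  Wide granules plateau the ridge, so inward yolk compaction is measured in
  edge mode on the outer yolk boundary.
* **Asters** — multi-scale Laplacian-of-Gaussian blobs with a
  range-relative threshold (scale invariant), intensity-weighted centroid
  refinement, and non-maximum suppression at the minimum σ.  Supplying the
  oocyte mask flattens the exterior so the cell boundary step cannot fire
  the detector.  Density is count per 10⁵ μm² of oocyte area.
* **Contraction domains** — final clusters are labeled; every pixel is
  assigned to its nearest cluster by exact Euclidean distance transform
  (ties to the lowest label, matching the brute-force oracle pixel for
  pixel); domains are the assignment restricted to the initial network
  mask.  The linear size ξ of a domain is its maximum axis-aligned extent,
  chosen so that a domain spanning the whole patch reports the system size
  (a Feret/diagonal definition would overreport a square field by √2);
  ξ1 ≥ ξ2 are the two largest, with ξ2 = ξ1 when a single domain exists.
  Classification is `large_scale` iff ξ1 ≥ 0.7 × field size (boundary
  inclusive — the CLI also reports the call at a 0.6 cutoff as a
  sensitivity check), else `local`.
* **Event metrics** — fusion histograms (default 10 min bins) with an
  optional nested random subsample emulating the practice of following
  10–20 granules; the mean-area series masks granule-free frames as NaN;
  the depletion ratio counts pre-activation granules with no overlapping
  post-activation pixel (no registration — the egg is mounted); the chorion
  ratio detects the two concentric circular boundaries by Canny + circular
  Hough voting and reports outer/inner diameter, returning 1.0 when only a
  single (coincident) boundary is detectable.

## Problem sizes and reproducibility

The default maturation run is 60 frames at 60 s intervals, rendered at
1 μm/px (624² pixels); an end-to-end segmentation+tracking pass takes about
half a minute on one core.  The simulated hour compresses the several-hour
maturation window; since the fusion calibration is defined per run, the
compressed clock does not change the targeted area factor.  All randomness
flows from a single integer seed; identical (parameters, seed) give
bit-identical frames and tables.

`scripts/acceptance.py` recomputes, from scratch: ξ1 of a global-contraction
series on the default patch (expected near the 200 μm system size), the
voxel-count GV/oocyte volume percentage (expected ≈1.5), and the end-to-end
mean-area factor of a default maturation run (expected ≈2).

## What the tests do and do not show

The generator shares its statistical structure with the real data —
granule sizes, packing density, channel contrast logic, motion scales, the
aster wave — but not its nuisance structure: no photobleaching, stage
drift, uneven illumination, depth-dependent scattering, shape irregularity,
or segmentation-confusing texture inside granules.  Passing the suite
demonstrates that the measurement operators are correct (they recover known
truth at realistic noise), not that the default thresholds transfer
unchanged to arbitrary microscopes; thresholds and minimum areas are
exposed as parameters for that reason.

## Known limitations

* The fusion rate is constant after GVBD; no spatial gradient of fusion
  (the animal-pole enrichment of fusion is not emulated).
* The blastodisc itself is not rendered; blastodisc clearance is testable
  only through the generic edge-velocimetry machinery.
* Aster fusion/splitting dynamics are not simulated (counts only).
* The cortical-granule rim exclusion undercounts Cg within 2 μm of the
  cortex, mirroring the corresponding artifact in real analyses.
* `segment_oocyte`'s convex-hull step assumes a convex cross-section.
* The chorion detector assumes near-circular boundaries and integer-pixel
  Hough radii (≈1–2% quantization at typical radii).
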