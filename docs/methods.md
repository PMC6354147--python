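# Methods

This note records the models, numerical choices, and known limitations of
`sectmorph`. All quantitative statements here are computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from external data.

## The experiment being emulated

A cohort of grafted-bone specimens is measured twice: once on a physical
stained section (histomorphometry) and once on virtual sections through a
micro-CT-like volume. The virtual section *matched* to the physical one is
found by search; four further sections are derived from it — parallel
offsets of ±4 pixels (±79 µm at the 19.75 µm pixel pitch) along the plane
normal, and rotations of ±10° about the in-plane vertical axis as seen from
the occlusal view. Each image is segmented into bone / graft / noncalcified
and summarized as percent area of a centered 4 × 4 mm region of interest.
Agreement between paired series of percent areas (across specimens) is then
quantified per phase, in two blocks: reference vs each of the five virtual
sections, and matched section vs the four perturbed ones.

The real specimens behind this design are not available; the package's claim
is therefore *structural*: under a synthetic cohort with realistic spatial
statistics, the matched plane attains distinctly higher concordance than any
perturbed plane. No attempt is made to reproduce specific published
coefficient values.

## Phantom model

* **Bone** is a stationary correlated binary field: white Gaussian noise
  smoothed by an isotropic Gaussian kernel of width `correlation_length`
  (default 60 µm ≈ 3 voxels), thresholded at the empirical quantile that
  realizes `bone_fraction_target` (default 0.30) exactly up to ties. The
  correlation length is the single knob controlling how quickly parallel
  sections decorrelate, i.e. how plane-sensitive the measurement is.
* **Graft** is a set of non-overlapping spheres placed by rejection sampling
  into non-bone space; radii are normal (mean 80 µm, SD 20 µm) truncated at
  one voxel. Hard-sphere packing jams near the target fraction, so after 200
  consecutive rejections the candidate radius scale shrinks by 0.7 (floor one
  voxel) — granular grafts are polydisperse, and small fragments fill
  residual gaps. Placement stops once the realized fraction is within 2%
  (relative) of `graft_fraction_target` (default 0.15); if the attempt budget
  (default 500 000) runs out first, the generator fails loudly, naming the
  realized fraction. Realized fractions are recorded in `meta`.
* **Rendering**: each phase gets a mean grayscale value (noncalcified 50,
  bone 120, graft 220 — hydroxyapatite attenuates more than mineralized
  bone), plus i.i.d. Gaussian noise (default SD 10) and a Gaussian blur
  (default 10 µm ≈ 0.5 voxel) standing in for the scanner point-spread.
* **Histology proxy**: the phase section at a (possibly perturbed) plane
  with a stated fraction of labels flipped uniformly to another phase
  (default 2%, no geometric perturbation). The proxy is label-level noise by
  design: the physical measurement is itself a segmentation, so
  inter-modality disagreement is modeled where it lives. Staining contrast,
  the ~30 µm physical section thickness, and preparation distortion are
  *not* modeled; sections are ideal planes.

All three random streams (structure, rendering, histology) derive from one
`seed` via `SeedSequence`, so every artifact is bitwise reproducible.

### What the phantom does not capture

Real trabecular bone is anisotropic and connected; the Gaussian-field bone
phase is isotropic and has no plate/rod architecture. Real cohorts share
surgical site geometry (cortical walls, socket shape) that induces
between-specimen correlation; phantom specimens are fully independent.
Passing tests therefore demonstrate the *mechanics* of section-plane
sensitivity and the correctness of the statistics — not quantitative
fidelity to any animal model.

One consequence measured during development: the *absolute* between-plane
difference of percent areas does not fall as the correlation length grows
(slice-fraction variance grows in step and cancels the smoothness gain), but
the *relative* sensitivity — mean |Δ| normalized by the between-slice SD,
which is what drives concordance — falls monotonically. The property test
asserts the normalized form.

## Geometry

World coordinates are micrometres; arrays are indexed `[z, y, x]`; voxel
`(iz, iy, ix)` has its center at `origin + (ix, iy, iz)·spacing`. A
`SectionPlane` carries an orthonormal right-handed frame `(u, v, n = u × v)`,
pixel pitch and extent; pixel `(r, c)` samples
`origin + (c − (cols−1)/2)·pitch·u + (r − (rows−1)/2)·pitch·v`. The
voxel-center convention makes axis-aligned extraction reproduce the raw
array slice exactly, which anchors the geometry tests.

Offsets displace the origin along `+n` (positive = buccal). Rotations pivot
about `v` (the apico-occlusal axis) through the image center — the natural
reading of a rotation "seen from the occlusal view" that keeps the image
center fixed; positive is clockwise in that view. Offset and rotated
variants are always derived independently from the matched plane, never
chained. Out-of-volume samples are masked invalid rather than zero-filled
(zero-filling would inflate the noncalcified fraction); percent areas use
valid pixels only.

Grayscale extraction supports trilinear and nearest interpolation (labels:
nearest only, since they are categorical). Trilinear extraction is linear in
the volume and exact at voxel centers.

## Segmentation

Default thresholds are the two-threshold multi-class Otsu solution computed
per image over valid pixels (the field's standard replacement for manual
luminance thresholding); darkest band → noncalcified, middle → bone,
brightest → graft, remappable. A manual override map (labels plus a mask of
supplied pixels) replaces automatic labels where provided, mirroring the
manual touch-up of ambiguous boundaries. No morphological cleanup is
applied by default. Partial-volume effects are intentionally out of scope.

With noise at ¼ of the minimum inter-phase mean gap, each class mean lies
2 SD from the midpoint threshold, so per-pixel accuracy has a Bayes floor
near 98% — measured accuracy with Otsu at the default means is ≈ 97.8%
(blur off). Noiseless renderings are recovered pixel-perfectly.

## Morphometry and overlap

Percent areas are exact counts over valid ROI pixels followed by one
division; they sum to 100 up to float rounding. The ROI is fixed in plane
coordinates (centered), recorded in provenance. The concordance area rate
reports per-phase Jaccard (with the Dice companion, `D = 2J/(1+J)`) over
jointly valid ROI pixels; phases absent from both maps are NaN and excluded
from averages. Equal cumulative areas do not imply overlap — a constructed
counterexample fixture (equal areas, shifted regions, Jaccard 0) encodes
this distinction.

## Plane search

The search runs over five parameters relative to an initial plane: offset
along the normal, tilts about `u` and `v`, in-plane rotation, and in-plane
translation along `u` (defaults: offset ±6 px, tilt about `v` ±15°, others
pinned). A coarse grid (13 offset × 11 tilt points by default) is followed
by bounded Nelder–Mead refinement. Because the mean-phase-Dice objective is
piecewise constant in sub-voxel moves, a single simplex can stall on a
plateau; refinement therefore restarts from the top-5 grid points and keeps
the overall best (early exit at score 1.0). Convergence tolerances: 0.1 on
the parameter vector, 200 iterations per start. The returned score always
equals re-scoring the returned plane, and never falls below the best grid
score. Mutual information is available for grayscale references.

Planted-plane experiments (64³ phantoms, planted offsets up to ±4 px and
tilts up to ±10°) recover the plane within 1 pixel and 1° in 20/20 seeded
replicates under the default search spec.

## Agreement statistics

* **CCC**: Lin's estimator with 1/n moment estimators. CI by the
  inverse-hyperbolic-tangent transform with Lin's asymptotic SE in its
  corrected form, back-transformed; 95% two-sided by default. Degenerate
  inputs: both series constant → error; one constant → 0 with a flag;
  |CCC| = 1 → point interval. Empirical coverage at n = 16 bivariate-normal
  pairs (population CCC 0.8, 500 simulations) is ≈ 94%.
* **Mean Δ ± SD**: first-listed series minus comparator; sample SD (n−1).
  The sign convention is recorded in every output row.
* **Bland–Altman**: per-pair mean vs difference, bias ± 1.96 SD limits.
* **ICC**: two-way, absolute-agreement, single-measure, from the standard
  mean-squares decomposition — the comparator statistic only (it presumes
  equal marginal distributions, which is precisely what CCC does not).

Invariants asserted by tests: |CCC| ≤ |r|; CCC symmetric under series swap
and invariant under a common positive affine map, but not under shifting one
series; Δ antisymmetric under swap.

## Study pipeline

Per specimen: derive an independent seed (`SeedSequence(master).spawn()[i]`),
draw per-specimen bone/graft fraction targets from truncated normals around
the phantom defaults (SD 0.05 / 0.03, clipped to [0.05, 0.6] / [0.02, 0.35])
— real cohorts vary biologically, and without between-specimen variance
every agreement coefficient is degenerate — then generate, render, take the
reference proxy at the mid-volume mesiodistal plane, obtain the matched
plane (fast mode: the known generating plane; full mode: plane search),
derive the four perturbed planes, segment and measure all six images.
Tables mirror the two comparison blocks (5 + 4 rows) per phase; Bland–Altman
point sets are emitted per comparison. The whole report is a deterministic
function of the config and master seed, and the tables are recomputable from
the saved `measurements.csv` alone.

`sweep_perturbation` generalizes the fixed ±4 px / ±10° design to arbitrary
offset/angle lists, reporting CCC and mean |Δ| per level; mean |Δ| of percent
bone area grows monotonically over offsets {1, 2, 4, 8} px (Spearman 1.0 on
replicate means in the packaged experiments).

## Problem sizes

Packaged experiments run on 64³ phantoms (≈ 1.26 mm cubes at 19.75 µm pitch)
with 16 specimens per study and 20 replicate studies for the dominance
experiment, 8 specimens per replicate for the offset sweep; these sizes give
stable replicate statistics for the qualitative claims being tested. The
phantom default is 160³ (≈ 3.2 mm, so a 4 × 4 mm ROI is clipped to the
volume), with 256³ available for full-ROI work.

## Known limitations

* Plane search validation is phantom-only; no parameter-level ground truth
  exists for manual matching on real data.
* The histology proxy has no deformation model, so the search problem is
  rigid by construction; deformable 2D–3D registration is a non-goal.
* The inter-modality bias visible in study outputs (a few percent of area)
  is the systematic difference between label-level truth and threshold
  segmentation of a blurred rendering; it is shared across all virtual
  sections and does not affect the between-plane comparisons.
* NRRD I/O is a minimal raw-encoding subset (enough for round trips with
  spacing and origin); use the TIFF path for interchange with other tools.
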