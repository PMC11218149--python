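# Methods

## Problem

Building a 3D model of a pediatric renal tumor (nephroblastoma / Wilms'
tumor) and the surrounding neoplastic kidney requires a voxel-level
segmentation of a CT volume. Done fully by hand this takes an expert many
hours; done fully automatically it fails, because these tumors are large,
heterogeneous, and deform the normal anatomy far beyond what population-
trained networks cope with. `slicefill` implements the intermediate
regime: the expert annotates only every (g+2)-th axial section and an
automatic method completes the withheld sections in between. The single
integer *gap* g trades annotation effort against accuracy.

## The gap schedule and the time-saving model

Slices tile into blocks `[manual, g × automatic, manual]`, so consecutive
blocks do not share boundary slices. For a stack whose length is a
multiple of g+2 the automatic fraction is exactly

    time_saving(g) = g / (g + 2)

which is also the estimated expert time saving under the assumption that
every section costs the same annotation time (g=1 → 33 %, g=5 → 71 %,
g=8 → 80 %, g=10 → 83 % after integer rounding). A truncated final block
keeps its last slice manual, so every withheld slice is bracketed by
manual slices on both sides — a precondition for interpolation-style
completion.

Schedules can be tiled over the *annotated extent* (the slice range where
the anatomy is present, `extent="auto"`) rather than the whole stack.
This mirrors how an expert actually works — annotating from the first to
the last section where the structure appears — and pins the appearance
and disappearance of the anatomy with manual sections. Slices outside the
extent are trivially empty and are marked manual at no cost.

## Completion backends

**Shape-based interpolation (`interp`).** For each structure, every
annotated 2D section is converted to a signed Euclidean distance field
(negative inside; exact EDT via `scipy.ndimage`). A withheld slice j
bracketed by manual slices a < j < b gets the linear blend
`(1−t)·SDF_a + t·SDF_b`, `t = (j−a)/(b−a)`, thresholded at zero. Where
two structures claim a pixel, the smaller interpolated distance wins;
exact ties go to the lower label code. The method is deterministic,
spacing-aware, and *exact* for anatomy that is constant across slices —
which makes it both a useful baseline and a reference oracle for the
learned backend. When a structure is present on one bracketing slice and
absent on the other, the absent side is represented by a constant equal
to the present side's inradius, so the structure shrinks progressively
and collapses near the midpoint instead of vanishing instantly; this
one-sided convention is the main approximation of the backend and the
dominant error source at large gaps.

**Per-volume overfit network (`net`).** A compact 2D U-Net — encoder of
`depth` (conv3×3 → instance norm → ReLU)×2 blocks with 2×2 max-pooling,
mirrored decoder with nearest-neighbour up-sampling and skip
concatenation, 1×1 classification head — is trained *only on the manual
sections of the one volume being completed*. Deliberate overfitting is
the point: the network memorises this patient's anatomy and intensity
statistics and interpolates them across the gap. Withheld sections never
enter a batch (instrumented and asserted in tests), and manual sections
are copied verbatim into the output, so completion can only change
withheld slices. The historical training regime of the workflow this
package reimplements is 200 epochs at batch size 16; those are the
defaults, while the remaining choices it leaves open are ours: Adam at
1e-3, cross-entropy plus soft-Dice loss over the foreground classes, and
per-volume z-score intensity normalisation. A leave-one-patient-out
full-supervision mode (`train_full_supervision`) provides the fully
automatic baseline: train on every section of every other patient,
segment the held-out patient from scratch.

The network is written directly on numpy (im2col convolutions, hand-
derived backward passes, Adam). This keeps the package free of deep-
learning framework dependencies, bit-deterministic under a seed, and fast
enough on one CPU core for the per-volume regime, where a training set is
a handful of 2D sections. Gradient correctness is verified in the test
suite against central finite differences (directional derivative,
relative error < 1 % at small step). The default scaled-down spec
(depth 3, 16 base channels, ≈ 10⁵ parameters) trains one phantom volume
at gap 1 in under a minute on a desktop CPU; a `FULL_SCALE_SPEC` preset
(depth 4, 64 base channels) is provided for users with more compute but
is not exercised by any test.

## Evaluation

The Dice similarity index is `2A / (2A + B + C)` with A the voxels common
to prediction and reference and B, C the voxels unique to each —
equivalently `2|X∩Y| / (|X|+|Y|)`. Both masks empty is defined as Dice
1.0 (perfect agreement on absence) with a warning, keeping the metric
total. Evaluation can cover all slices (the default; manual slices are
verbatim copies, so this measures the quality of the delivered volume) or
withheld slices only (measuring only what the completion produced).
Reported tables round to 2 decimals, half-up; time savings round to
integer percent. The *crossing gap* — the largest gap at which a sweep's
mean Dice still matches a reference level such as inter-rater agreement —
is computed on 2-decimal-rounded values, because "matching" is defined at
the resolution of the published tables.

## The synthetic cohort

The original 14-scan clinical cohort is not distributable, so all
image-level experiments run on a phantom generator that emulates its
salient geometry: one kidney-shaped ellipsoid of parenchyma whose volume
is largely replaced by a big, lobulated, heterogeneous tumor, leaving a
thin crescent of kidney tissue beyond a 2 mm margin. Default geometry is
a 24×64×64 grid at 4×1×1 mm (thick sections, the annotation unit, vs
sub-voxel in-plane), kidney semi-axes 44×28×28 mm, tumor radius 20 mm
elongated ×2 along the slice axis so the mass spans most of the kidney's
extent, with low-order angular lobulation (amplitude 0.12), soft-tissue
intensities (background 35, tumor 70 ± 12 texture, kidney 120), 1 mm
partial-volume blur and additive Gaussian noise (σ = 10). Cohorts sample
per-patient geometry (tumor radius scale 0.7–0.9, kidney scale 0.9–1.1,
3 mm in-plane and 4 mm axial center jitter) deterministically from a
seed. The axial jitter also decorrelates the slice-sampling phase across
patients, which matters when averaging gap sweeps.

A second rater is simulated by displacing each structure's boundary with
a smooth Gaussian random field (correlation length 6 mm) applied to the
signed distance; one sigma in millimetres controls the disagreement, and
`calibrate_rater` bisects it until the Monte-Carlo mean Dice against the
reference hits a target — the study regime being ≈ 0.95 agreement for
tumor and ≈ 0.87 for the thin kidney crescent (the same displacement
costs the crescent far more Dice, which the calibration absorbs).

What the phantom does *not* emulate: realistic CT noise spectra and
artifacts, organ neighbourhoods and fat planes, multi-phase contrast,
fragmented parenchyma, and the full inter-patient variability of real
tumors. Passing the synthetic studies therefore shows that the
implementation behaves as the method intends under controlled geometry —
not that it reaches any particular accuracy on clinical data.

## Study problem sizes

The packaged experiments use deliberately desk-scale sizes, chosen so the
whole suite runs on one CPU core in minutes: 3-patient cohorts at the
default 24×64×64 geometry, the scaled-down network spec, 25–30 training
epochs, and gap sweeps over {1,…,10} (interpolation) or {1, 5, 10} × 3
seeds (network). The published per-patient benchmark tables of the
original clinical study are shipped as data and their aggregation is
recomputed, but the clinical per-patient Dice values themselves cannot be
reproduced without the original CTs.

## Numerical and design choices

- **Axis convention**: internal order is (slice, row, col) with the slice
  axis the scanner's axial axis, located from the NIfTI affine / NRRD
  direction matrix by dominant component; oblique reorientation is out of
  scope. Indices are 0-based, slice intervals half-open.
- **Label codes** are fixed at 0/1/2 (background / neoplastic kidney /
  tumor); foreign files can supply a relabel map.
- **Truncated schedule blocks** force the last slice manual (bracketing
  guarantee); the original workflow's handling of partial blocks is not
  documented, so this is a repository convention.
- **Tie-breaks** in multi-structure interpolation are deterministic
  (smallest distance, then lowest code).
- **Determinism**: every stochastic component (phantom, rater fields,
  weight init, batch shuffling) draws from an explicit seed;
  fixed seed + config + data reproduces losses and predictions bitwise on
  a given platform.
- **Instance normalisation** (per-sample, per-channel) is used instead of
  batch norm so that predictions are independent of batch composition and
  training is deterministic under reordering.
- **Both-empty Dice = 1.0** keeps per-slice evaluation total; empty
  evaluation *domains* (no slices selected) are an error instead.

## Known limitations

- The interpolation backend degrades sharply once the gap approaches the
  axial scale of anatomical change, and its one-sided vanishing
  convention misplaces structure end-caps by up to half a bracket.
- The numpy network is single-core and has no augmentation, scheduler, or
  early GPU path; it is sized for per-volume overfitting, not for
  population-scale training.
- The fully automatic leave-one-out baseline on 3-phantom cohorts is a
  functional contract check, not a meaningful estimate of automatic
  segmentation accuracy.
- Vascular and urinary structures, multi-phase registration, and MRI are
  out of scope.
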