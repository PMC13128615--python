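# Methods

## The measurement model

The quantity of interest is the cumulative internode length of a seedling's
main stem: the summed length of all internodes from the cotyledon node to
the apical growth point. The package assumes an upstream segmentation
stage has already produced a class mask in which the visible internode span
is class 1 (branches/leaves are class 0, the cotyledon node and everything
below it class 2, background 255). Measurement then proceeds:

1. **Undistortion.** Images are corrected with the Brown–Conrady
   radial–tangential model `(k1, k2, p1, p2, k3)`: each output pixel maps
   through the forward distortion model and samples the input bilinearly
   (`scipy.ndimage.map_coordinates`). With all-zero coefficients the image
   is returned unchanged. Calibration parameters are consumed, not
   estimated; checkerboard calibration is out of scope.
2. **Mask selection and cleanup.** The class-1 pixels are opened with a
   disk (radius 1 px by default), 8-connected components smaller than
   50 px are dropped, and if several components survive only the largest is
   kept (cultivation is one seedling per tray cell, so one main stem per
   image; a warning records the event). Both thresholds are exposed in the
   run configuration.
3. **Thinning.** The classic two-subiteration Zhang–Suen algorithm
   iterates until fixpoint, yielding a single-pixel-wide,
   connectivity-preserving skeleton. The implementation is vectorized
   NumPy; `skimage.morphology.skeletonize(method="zhang")` serves as an
   independent cross-check in the test suite, never as the implementation.
4. **Path extraction.** Skeleton endpoints are pixels with exactly one
   skeleton neighbor. The centerline is the longest geodesic (BFS over the
   8-neighbor pixel graph) between any two endpoints, which implicitly
   prunes short side spurs left by thinning. The path is oriented
   basal-end first (largest row index, i.e. lowest in the image). A closed
   loop (no endpoints) is a topology error; disjoint skeleton fragments
   fall back to the largest with a warning.
5. **Length.** Pixel arc length is the polyline sum
   `L_px = Σᵢ ‖pᵢ₊₁ − pᵢ‖₂` (axis steps 1, diagonal steps √2), converted
   to millimetres by the longitudinal calibration factor: `L = k · L_px`.
   `k` is a single scalar; perspective variation across the field of view
   is out of scope.
6. **Grading.** Grade I iff `100 ≤ L ≤ 130` mm, Grade II iff
   `130 < L ≤ 150` mm, OUT otherwise, following the interval notation
   literally (130 mm is Grade I, 150 mm is Grade II, both boundary values
   belong to the lower band). OUT is a single class; a diagnostic records
   whether an OUT seedling was stunted (short) or leggy (long).

**Occlusion principle.** Occlusion gaps are never bridged: only visible
internode pixels are measured, mirroring an annotation rule in which only
visible stem parts are labeled. Occlusion therefore biases measurements
*downward*, and measured length is monotone non-increasing in the occluded
fraction — a property the tests assert directly.

## Error budget of the skeleton length

Two systematic effects act on step 5, in opposite directions:

* **End-cap erosion.** Thinning a stroke of width `w` retracts each end of
  the skeleton by about `w/2`, shortening the measurement by roughly one
  stem width (≈ 6–7 px at the default 0.5 mm/px scale: −2 to −3 %).
* **Chain-length inflation.** The Euclidean length of a digital 8-chain
  overestimates a straight segment tilted by θ from the nearest axis by a
  factor `cos θ + (√2 − 1) sin θ`, ≈ +3 % at 5° and +8 % at 24°, with no
  dependence on resolution. For near-vertical stems the two effects
  largely cancel; strongly bent or tilted stems are overestimated before
  occlusion and underestimated after it. No smoothing correction is
  applied: the reported length is the raw polyline sum over the skeleton.

## The synthetic generator

`synthetic.make_seedling` builds seedlings whose ground truth is exact by
construction, standing in for field data that cannot be shipped:

* the stem centerline is a cubic Bézier bowed sideways by
  `curvature × length`; integrating a 4096-point polyline and rescaling
  uniformly (arc length is linear under uniform scaling) hits the target
  length exactly, far inside the 0.5 % truth tolerance;
* the centerline is stamped with disks of the stem width, drawn from the
  2.8–3.5 mm diameter range of nursery stock at grading age, converted by
  the synthetic camera scale `k_synth` (default 0.5 mm/px);
* elliptical class-0 leaf blobs attach along the stem *behind* it;
  occlusion is realized separately by overwriting a contiguous run of stem
  pixels (a leaf in front), grown symmetrically around a random interior
  point until the requested pixel fraction is reached, so the realized
  fraction is accurate to about one stem width of pixels;
* a class-2 blob (cotyledon node and roots) sits below the basal endpoint;
* the rendered image is flat class colors plus Gaussian texture noise.

The default curvature range (bow amplitude 0.01–0.08 of stem length,
i.e. base tangent tilts up to ≈ 13°) models staked, roughly upright
seedlings and was chosen so that the chain-length inflation above stays
within the measurement chain's few-percent error envelope; strongly
drooping stems are deliberately outside the generated regime and would be
overestimated (see limitations). `make_batch` stratifies true lengths over
the grade bands — default mix 41:60:43 over I:II:OUT as in a 144-seedling
grading trial — drawing uniformly inside each band (OUT splits evenly
between a stunted 80–100 mm and a leggy 150–180 mm range, spanning the
80–180 mm envelope used in the recovery experiments).

What the generator does **not** emulate: perspective and out-of-plane
inclination (stems live in the image plane; `k` is exact by construction),
segmentation errors of an upstream network (masks are clean), textured
backgrounds, multiple plants per frame, and fallen or missing cotyledons.
Passing tests therefore validate the geometry/measurement chain, not
robustness to segmentation noise.

## Augmentation policy

Brightness jitter is multiplicative `(1 + f)` with `f ∈ [−0.2, 0.2]`;
noise is additive zero-mean Gaussian with σ ∈ [5, 25] intensity units;
blur uses a 3×3 Gaussian kernel sampled at integer offsets, normalized to
sum 1, with σ ∈ [0.1, 2.0] and reflected borders. All three are
photometric and leave masks untouched; the fourth registered technique,
horizontal flip, transforms image and mask jointly. `expand_dataset`
keeps each original and adds two copies, each composing two distinct
randomly chosen techniques, tripling the dataset (1,100 → 3,300). Results
are rounded half-even and clipped to the 8-bit range after every step.

## Reference network blocks

These are forward-only, correctness-first NumPy implementations (no
gradients, no runtime integration):

* **Deformable convolution.** Offsets arrive as a `2N × H × W` field
  (row/col displacement per sampling position, `N = kh·kw`); fractional
  positions are resolved by bilinear interpolation and positions outside
  the padded input read as zero, matching the original deformable-conv
  formulation. With all-zero offsets the operation is identical to the
  regular convolution to machine precision — asserted against a naive
  quadruple-loop oracle.
* **SIoU angle cost.** `Λ = 1 − 2 sin²(arcsin(c_h/σ) − π/4)` with `c_h`
  the vertical and `σ` the Euclidean center distance; the ratio is clamped
  into [0, 1] against float error and coincident centers (`σ = 0`, where
  the formula is undefined) are defined to carry no penalty. Λ is 0 for
  axis-aligned center lines, 1 at 45°, and symmetric under α ↔ 90° − α.
  The full SIoU loss (IoU, distance and shape terms) is provided as an
  optional composite; the angle cost is the tested contract.
* **Haar wavelet downsampling.** Each non-overlapping 2×2 block
  `[[a, b], [c, d]]` maps to `A, H, V, D = (a±b±c±d)/2`; the 1/2 factor
  makes the transform orthonormal so energy is conserved exactly and the
  inverse is exact (odd sizes are reflect-padded, recorded and undone).
  `hwd_downsample` concatenates the four bands along channels
  (`C×h×w → 4C×h/2×w/2`), losing nothing — unlike 2×2 max pooling, which
  maps a one-pixel line and its one-pixel shift to identical outputs.
  Adaptive re-weighting of the detail bands is not implemented; no
  reproducible definition of it is available.

## Evaluation metrics

Pixel precision/recall use per-class TP/FP/FN counts; a class absent from
both masks scores 1.0 by convention, absent from one side 0.0. Average
precision integrates the precision–recall curve of confidence-sorted
predictions with the all-point interpolated envelope by default (the
classic 11-point rule is available via `method="11point"`); mAP@0.5
averages per-class AP at a mask-IoU match threshold of 0.5. N = 3
annotation classes.

## Numerical and design choices

* **Rasterization**: a pixel belongs to a polygon iff its center is inside
  under the even-odd rule with half-open crossings, so abutting polygons
  never double-fill; later shapes overwrite earlier ones (annotation
  stacking order); zero-area polygons are skipped with a warning.
  Background is encoded as 255 so class ids 0/1/2 keep their literal
  annotation meaning.
* **Coordinates**: 0-based `(row, col)` everywhere internally; labelme's
  `(x, y)` is converted at the I/O boundary.
* **Seeding**: one global seed; per-stage generators derive from it via
  `(seed, sha256(label))` seed sequences, so adding a stage never shifts
  another stage's stream. Same seed → bit-identical outputs everywhere.
* **Empty masks** (fully occluded stems, denoising removed everything)
  yield length 0, grade OUT and an `empty_mask` flag rather than an error;
  per-file errors in batch mode are logged and skipped unless `--strict`.
* **Grading summary**: the mean success rate is count-weighted (total
  diagonal over total count) by default; the unweighted across-grade mean
  is reported alongside since both summaries are in common use.

## Problem sizes

The test suite and `scripts/acceptance.py` run entirely on synthetic
inputs: netblock checks on grids up to 16×16, the expansion law on 1,100
grayscale 256×256 images, length recovery on 100 unoccluded seedlings
spanning 80–180 mm, and two 144-seedling stratified grading experiments
(unoccluded, and 15 % occlusion). On one CPU the whole acceptance run
takes well under a minute.

## Known limitations

* The raw chain-length estimator has the angle-dependent bias described
  above; stems tilted far from vertical are overestimated. A resolution-
  independent effect, it dominates once bow amplitudes exceed ~10 % of
  stem length.
* Disconnected visible stem fragments under occlusion are resolved by
  measuring the largest fragment, not by summing fragments; heavily
  occluded seedlings are therefore strongly underestimated (the 15 %
  occlusion experiment quantifies this).
* `k` is a global scalar: no per-pixel metric scale, no perspective or
  out-of-plane correction.
* The reference blocks are forward numerics for verification; they are not
  a training framework and carry no claims about detector accuracy.
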