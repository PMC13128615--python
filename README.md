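# internode

Tools for measuring and grading the **cumulative internode length** of
tomato seedlings from segmentation masks.

Nurseries grade seedlings before transplanting so that each batch grows
uniformly. Traits like leaf color or canopy width drift with water, light
and temperature; the summed length of the internodes along the main stem —
from the cotyledon node to the apical growth point — is a far more stable
vigor indicator. A vision system segments the visible internode span of
each seedling; this package covers everything around and after that
segmentation step:

* **io_formats** — labelme polygon JSON → integer class masks
  (0 = branches/leaves, 1 = internode span, 2 = cotyledon node and below;
  background 255), calibration configs, result CSVs.
* **synthetic** — seedlings with exactly known centerline length (Bézier
  stem, leaf blobs, controllable occlusion), so the whole chain can be
  validated without field data.
* **augment** — the dataset-expansion policy: brightness ±20%, Gaussian
  noise σ ∈ [5, 25], 3×3 Gaussian blur σ ∈ [0.1, 2.0], horizontal flip;
  two composed techniques per copy, two copies per original (3× expansion).
* **netblocks** — framework-free reference numerics for three detector
  building blocks: deformable convolution
  `y(p₀) = Σₙ w(pₙ) x(p₀ + pₙ + Δpₙ)` with bilinear sampling, the SIoU
  angle cost `Λ = 1 − 2 sin²(arcsin(c_h/σ) − π/4)`, and orthonormal Haar
  wavelet downsampling (A/H/V/D bands, lossless 2× downsampling).
* **measure** — the measurement chain: Brown–Conrady undistortion →
  class-1 extraction → morphological denoising → Zhang–Suen thinning →
  longest-geodesic skeleton path P = {p₁…pₙ} → arc length
  `L_px = Σ‖pᵢ₊₁ − pᵢ‖₂` → physical length `L = k·L_px` with the
  longitudinal calibration factor k (mm/px).
* **grading** — grade bands over L (mm): Grade I `[100, 130]`,
  Grade II `(130, 150]`, everything else OUT; confusion-matrix /
  success-rate / length-error bookkeeping for grading experiments.
* **metrics** — pixel precision/recall, average precision (all-point
  envelope or 11-point) and mAP@0.5 for segmentation evaluation.

## Worked example

```python
from internode import make_seedling, measure_seedling, CalibrationProfile

seedling = make_seedling(length_mm=120.0, curvature=0.05,
                         occlusion_fraction=0.1, k_synth=0.5, rng_seed=42)
print(f"true length : {seedling.true_length_mm:.2f} mm "
      f"({seedling.true_length_px:.1f} px at k = {seedling.k_synth} mm/px)")
print(f"occlusion   : {seedling.occlusion_fraction:.3f}")

calib = CalibrationProfile.identity(k=0.5)
result = measure_seedling(seedling.mask, calib)
print(f"measured    : {result.length_mm:.2f} mm "
      f"({result.length_px:.1f} px over {result.n_skeleton_px} skeleton pixels)")
print(f"grade       : {result.grade}")
```

prints

```
true length : 120.00 mm (240.0 px at k = 0.5 mm/px)
occlusion   : 0.104
measured    : 108.61 mm (217.2 px over 212 skeleton pixels)
grade       : I
```

The generated seedling is 120 mm long but a leaf hides 10.4% of its stem.
Only visible internode pixels are ever measured — occlusion gaps are not
bridged — so the skeleton measures 108.61 mm, an underestimate of roughly
the occluded fraction, still inside the Grade I band. With
`occlusion_fraction=0.0` the same seedling measures within ~2% of truth
(thinning erodes about half a stem width at each end; diagonal chain steps
slightly overestimate tilted runs).

The same chain is available from a shell:

```sh
internode --seed 5 synth --n 12 --out-dir data/
internode --seed 5 measure-batch --in-dir data/ --out measured.csv
internode evaluate --truth data/truth.csv --pred measured.csv --out report.json
internode blocks-demo
```

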