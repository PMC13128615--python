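"""Synthetic seedling masks and images with known centerline length.

Real seedling data for this task is scarce, so every downstream stage is
validated against generated seedlings whose ground truth is exact by
construction: the stem centerline is a cubic Bezier of known arc length
(class 1), elliptical leaf blobs (class 0) sit along the stem and can
occlude a contiguous run of it, and a cotyledon/root blob (class 2) sits at
the basal end. The generator emulates the cultivation conditions of the
grading problem: stem diameters of 2.8-3.5 mm, stems roughly upright with
gentle curvature, lengths spanning the grade bands.

Arc-length targeting: the Bezier is integrated as a dense polyline and
rescaled uniformly, which maps arc length linearly, so the target length is
met exactly (well inside the 0.5% tolerance the truth must satisfy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grading import GRADES, GradeBands, grade
from .io_formats import BACKGROUND, LabeledMask

_DENSE_SAMPLES = 4096

#: default stem-diameter range, mm (nursery stock at grading age)
STEM_DIAMETER_MM = (2.8, 3.5)

#: Lateral bow amplitude as a fraction of stem length. "Gentle" is bounded
#: by the chain-length discretization bias of the downstream measurement:
#: a digital 8-chain overestimates a segment tilted by theta from an axis
#: by about (sqrt(2)-1)*sin(theta), so tilts must stay within ~13 deg
#: (base tangent tilt = atan(3 * curvature) for the bow used here) for the
#: skeleton length to track the true centerline within a few percent.
#: Seedlings at grading age are staked upright, so this is also realistic.
DEFAULT_CURVATURE = 0.05
CURVATURE_RANGE = (0.01, 0.08)

#: length ranges (mm) per stratum for batch generation; OUT seedlings are
#: either stunted (short side) or leggy (long side)
OUT_SHORT_MM = (80.0, 100.0)
OUT_LONG_MM = (150.0, 180.0)


class GeometryError(ValueError):
    """The requested seedling does not fit a reasonable canvas."""


@dataclass(frozen=True)
class SyntheticSeedling:
    """One generated seedling: mask + rendered image + exact ground truth."""

    mask: LabeledMask
    image: np.ndarray
    true_length_px: float
    true_length_mm: float
    control_points: np.ndarray  # (4, 2) Bezier control points, (x, y) px
    stem_width_px: float
    occlusion_fraction: float
    seed: int
    k_synth: float

    @property
    def true_grade(self) -> str:
        return grade(self.true_length_mm)


def _cubic_bezier(ctrl: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = t[:, None]
    return (
        (1 - t) ** 3 * ctrl[0]
        + 3 * (1 - t) ** 2 * t * ctrl[1]
        + 3 * (1 - t) * t**2 * ctrl[2]
        + t**3 * ctrl[3]
    )


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def _paint_disks(mask: np.ndarray, param_map: np.ndarray,
                 centers_rc: np.ndarray, radius: float) -> None:
    """Stamp class-1 disks along the centerline, recording the first
    centerline parameter index that claims each pixel."""
    h, w = mask.shape
    r_int = int(np.ceil(radius))
    dr, dc = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    inside = dr**2 + dc**2 <= radius**2
    dr, dc = dr[inside], dc[inside]
    for idx, (r, c) in enumerate(centers_rc):
        rr = np.clip(np.rint(r + dr).astype(int), 0, h - 1)
        cc = np.clip(np.rint(c + dc).astype(int), 0, w - 1)
        fresh = mask[rr, cc] != 1
        mask[rr, cc] = 1
        param_map[rr[fresh], cc[fresh]] = idx


def _paint_ellipse(mask: np.ndarray, center_rc: tuple[float, float],
                   radii: tuple[float, float], angle: float, value: int) -> None:
    """Fill an ellipse with ``value`` only over background pixels."""
    from skimage.draw import ellipse

    rr, cc = ellipse(center_rc[0], center_rc[1], radii[0], radii[1],
                     shape=mask.shape, rotation=angle)
    sel = mask[rr, cc] == BACKGROUND
    mask[rr[sel], cc[sel]] = value


def make_seedling(length_mm: float = 120.0, curvature: float = DEFAULT_CURVATURE,
                  stem_width_px: float | None = None,
                  occlusion_fraction: float = 0.0, k_synth: float = 0.5,
                  rng_seed: int = 0, n_leaves: int = 3,
                  max_canvas: int = 4096) -> SyntheticSeedling:
    """Generate one seedling with exactly known centerline length.

    Parameters
    ----------
    length_mm : target centerline length; met exactly by construction.
    curvature : lateral bow amplitude of the stem as a fraction of its
        length (0 = perfectly straight and vertical).
    stem_width_px : stem thickness; default drawn from the 2.8-3.5 mm
        diameter range converted by ``k_synth``.
    occlusion_fraction : fraction of stem pixels overwritten by a leaf in
        front of the stem (a contiguous run in the stem interior).
    k_synth : mm-per-pixel scale tying pixel and physical truth together.
    rng_seed : all randomness (width, leaf placement, occlusion window
        center) flows from this seed; same seed -> bit-identical output.
    """
    if length_mm <= 0:
        raise ValueError(f"length_mm must be positive, got {length_mm}")
    if not 0 <= occlusion_fraction < 1:
        raise ValueError(f"occlusion_fraction must be in [0, 1), got {occlusion_fraction}")
    if k_synth <= 0:
        raise ValueError(f"k_synth must be positive, got {k_synth}")

    rng = np.random.default_rng(rng_seed)
    if stem_width_px is None:
        stem_width_px = rng.uniform(*STEM_DIAMETER_MM) / k_synth
    else:
        rng.uniform(*STEM_DIAMETER_MM)  # keep the draw order stable
    if stem_width_px < 1:
        raise ValueError(f"stem_width_px must be >= 1, got {stem_width_px}")

    target_px = length_mm / k_synth

    # unit-height bowed stem in math coords (y up), then uniform rescale
    side = rng.choice((-1.0, 1.0))
    ctrl = np.array([
        [0.0, 0.0],
        [side * curvature, 1.0 / 3.0],
        [side * curvature, 2.0 / 3.0],
        [0.0, 1.0],
    ])
    t = np.linspace(0.0, 1.0, _DENSE_SAMPLES)
    pts = _cubic_bezier(ctrl, t)
    scale = target_px / _polyline_length(pts)
    pts *= scale
    ctrl = ctrl * scale
    true_length_px = _polyline_length(pts)  # == target_px up to float rounding

    leaf_r = 3.0 * stem_width_px
    margin = stem_width_px + 2 * leaf_r + 8.0
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    width = int(np.ceil(xmax - xmin + 2 * margin))
    height = int(np.ceil(ymax - ymin + 2 * margin))
    if width > max_canvas or height > max_canvas:
        raise GeometryError(
            f"seedling needs a {height}x{width} canvas, exceeding {max_canvas}"
        )

    # math (x, y) -> image (row, col), basal end at the bottom
    cols = pts[:, 0] - xmin + margin
    rows = (ymax - pts[:, 1]) + margin
    centers_rc = np.stack([rows, cols], axis=1)
    ctrl_img = np.stack([ctrl[:, 0] - xmin + margin, (ymax - ctrl[:, 1]) + margin], axis=1)

    # resample the centerline to ~0.7 px spacing before stamping disks
    n_draw = max(2, int(true_length_px / 0.7))
    draw_idx = np.linspace(0, _DENSE_SAMPLES - 1, n_draw).astype(int)

    mask = np.full((height, width), BACKGROUND, dtype=np.uint8)
    param_map = np.full((height, width), -1, dtype=np.int32)
    _paint_disks(mask, param_map, centers_rc[draw_idx], stem_width_px / 2.0)

    # leaf blobs along the stem, not overwriting it (behind the stem)
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    for i in range(n_leaves):
        u = rng.uniform(0.2, 0.9)
        j = int(u * (_DENSE_SAMPLES - 1))
        leaf_side = -1.0 if i % 2 else 1.0
        offset = normals[j] * leaf_side * (stem_width_px / 2 + 0.7 * leaf_r)
        cx = cols[j] + offset[0]
        cy = rows[j] - offset[1]
        rx = leaf_r * rng.uniform(0.7, 1.1)
        ry = rx * rng.uniform(0.45, 0.7)
        _paint_ellipse(mask, (cy, cx), (ry, rx), rng.uniform(-0.6, 0.6), 0)

    # occlusion: a leaf IN FRONT of the stem overwrites a contiguous run
    realized_occlusion = 0.0
    if occlusion_fraction > 0:
        stem_sel = mask == 1
        params = param_map[stem_sel]
        total = int(stem_sel.sum())
        per_param = np.bincount(params[params >= 0], minlength=_DENSE_SAMPLES)
        target = occlusion_fraction * total
        center = int(rng.uniform(0.35, 0.65) * _DENSE_SAMPLES)
        lo = hi = center
        count = per_param[center]
        while count < target and (lo > 0 or hi < _DENSE_SAMPLES - 1):
            if lo > 0:
                lo -= 1
                count += per_param[lo]
            if count < target and hi < _DENSE_SAMPLES - 1:
                hi += 1
                count += per_param[hi]
        occluded = stem_sel & (param_map >= lo) & (param_map <= hi)
        mask[occluded] = 0
        realized_occlusion = float(occluded.sum() / total)
        # decorate the window with a leaf blob so the occluder looks leaf-like
        j = (lo + hi) // 2
        _paint_ellipse(mask, (rows[j], cols[j]),
                       (0.5 * leaf_r, 0.9 * leaf_r), rng.uniform(-0.6, 0.6), 0)

    # cotyledon node and roots below the basal endpoint (class 2)
    base_r, base_c = centers_rc[0]
    _paint_ellipse(mask, (base_r + stem_width_px, base_c),
                   (1.2 * stem_width_px, 1.6 * stem_width_px), 0.0, 2)

    image = _render(mask, rng)

    return SyntheticSeedling(
        mask=LabeledMask(mask),
        image=image,
        true_length_px=true_length_px,
        true_length_mm=k_synth * true_length_px,
        control_points=ctrl_img,
        stem_width_px=float(stem_width_px),
        occlusion_fraction=realized_occlusion,
        seed=int(rng_seed),
        k_synth=float(k_synth),
    )


_CLASS_COLORS = {
    BACKGROUND: (46, 42, 40),   # tray/substrate
    0: (58, 132, 62),           # leaves and branches
    1: (132, 186, 98),          # main stem (internode span)
    2: (148, 118, 82),          # cotyledon node and below
}


def _render(mask: np.ndarray, rng: np.random.Generator,
            noise_sigma: float = 6.0) -> np.ndarray:
    """Flat class colors + Gaussian texture noise, 8-bit RGB."""
    img = np.empty(mask.shape + (3,), dtype=float)
    for value, color in _CLASS_COLORS.items():
        img[mask == value] = color
    img += rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _stratum_counts(n: int, grade_mix) -> list[int]:
    """Largest-remainder apportionment of n over the three strata."""
    props = np.asarray(grade_mix, dtype=float)
    if props.shape != (3,) or not np.isclose(props.sum(), 1.0):
        raise ValueError("grade_mix must be 3 proportions summing to 1")
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


def make_batch(n: int, grade_mix=(41 / 144, 60 / 144, 43 / 144), rng_seed: int = 0,
               k_synth: float = 0.5, occlusion_fraction: float = 0.0,
               curvature_range: tuple[float, float] = CURVATURE_RANGE,
               bands: GradeBands | None = None) -> list[SyntheticSeedling]:
    """Generate ``n`` seedlings stratified by true grade.

    ``grade_mix`` gives the (I, II, OUT) proportions; the default mirrors a
    144-seedling grading trial with 41/60/43 per stratum. Lengths are drawn
    uniformly within each stratum's band (OUT splits evenly between stunted
    and leggy ranges), so each seedling's true grade matches its stratum.
    """
    bands = bands or GradeBands()
    counts = _stratum_counts(n, grade_mix)
    rng = np.random.default_rng(rng_seed)

    out: list[SyntheticSeedling] = []
    for stratum, count in zip(GRADES, counts):
        for _ in range(count):
            if stratum == "I":
                length = rng.uniform(*bands.grade_i)
            elif stratum == "II":
                # open lower bound: exactly 130 mm would still be grade I
                length = rng.uniform(np.nextafter(bands.grade_i[1], np.inf),
                                     bands.grade_ii_hi)
            else:
                length = (
                    rng.uniform(*OUT_SHORT_MM)
                    if rng.random() < 0.5
                    else rng.uniform(*OUT_LONG_MM)
                )
            out.append(
                make_seedling(
                    length_mm=float(length),
                    curvature=float(rng.uniform(*curvature_range)),
                    occlusion_fraction=occlusion_fraction,
                    k_synth=k_synth,
                    rng_seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return out
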