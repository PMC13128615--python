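"""The measurement chain: mask -> skeleton -> arc length -> millimetres.

Given a class mask whose class-1 region marks the visible cumulative
internode span of a seedling, the chain is

    undistort -> extract class-1 -> denoise -> Zhang-Suen thin ->
    order skeleton -> arc length (px) -> k * L_px (mm) -> grade

Occlusion gaps are never bridged: only visible internode pixels are
measured, so occlusion biases the estimate downward.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage import morphology

from .grading import GradeBands, grade
from .io_formats import CalibrationProfile, LabeledMask, SeedlingResult


class EmptyMaskError(ValueError):
    """The mask holds no usable internode pixels."""


class SkeletonTopologyError(ValueError):
    """The skeleton has no endpoints (e.g. it is a closed loop)."""


@dataclass(frozen=True)
class SkeletonPath:
    """Ordered single-pixel-wide centerline P = {p1, ..., pn}.

    ``pixels`` is an (n, 2) int array of (row, col); consecutive pixels are
    8-neighbors and the first pixel is the basal end (largest row index,
    i.e. lowest in the image).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] < 1:
            raise ValueError("path must be an (n, 2) array with n >= 1")
        steps = np.abs(np.diff(px, axis=0))
        if steps.size and (steps.max(axis=1) > 1).any():
            raise ValueError("consecutive path pixels must be 8-neighbors")
        if len(np.unique(px, axis=0)) != len(px):
            raise ValueError("path revisits a pixel")
        object.__setattr__(self, "pixels", px)

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return tuple(self.pixels[0]), tuple(self.pixels[-1])

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class MeasureParams:
    """Tunables of the measurement chain (defaults used throughout)."""

    min_component_px: int = 50
    opening_radius: int = 1
    bands: GradeBands = field(default_factory=GradeBands)


# ---------------------------------------------------------------------------
# undistortion (Brown-Conrady)
# ---------------------------------------------------------------------------

def distort_points(points_xy: np.ndarray, calib: CalibrationProfile) -> np.ndarray:
    """Apply the forward radial-tangential model to ideal pixel points."""
    pts = np.asarray(points_xy, dtype=float)
    k1, k2, p1, p2, k3 = calib.dist_coeffs[:5]
    xn = (pts[:, 0] - calib.cx) / calib.fx
    yn = (pts[:, 1] - calib.cy) / calib.fy
    r2 = xn**2 + yn**2
    radial = 1 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = xn * radial + 2 * p1 * xn * yn + p2 * (r2 + 2 * xn**2)
    yd = yn * radial + p1 * (r2 + 2 * yn**2) + 2 * p2 * xn * yn
    return np.stack([xd * calib.fx + calib.cx, yd * calib.fy + calib.cy], axis=1)


def undistort_points(points_xy: np.ndarray, calib: CalibrationProfile,
                     iterations: int = 20) -> np.ndarray:
    """Invert :func:`distort_points` by fixed-point iteration."""
    pts = np.asarray(points_xy, dtype=float)
    k1, k2, p1, p2, k3 = calib.dist_coeffs[:5]
    xd = (pts[:, 0] - calib.cx) / calib.fx
    yd = (pts[:, 1] - calib.cy) / calib.fy
    x, y = xd.copy(), yd.copy()
    for _ in range(iterations):
        r2 = x**2 + y**2
        radial = 1 + k1 * r2 + k2 * r2**2 + k3 * r2**3
        dx = 2 * p1 * x * y + p2 * (r2 + 2 * x**2)
        dy = p1 * (r2 + 2 * y**2) + 2 * p2 * x * y
        x = (xd - dx) / radial
        y = (yd - dy) / radial
    return np.stack([x * calib.fx + calib.cx, y * calib.fy + calib.cy], axis=1)


def undistort(image: np.ndarray, calib: CalibrationProfile) -> np.ndarray:
    """Remove lens distortion from an image (size preserved).

    Each output (ideal) pixel looks up its source location through the
    forward Brown-Conrady model and samples the input bilinearly; with
    all-zero coefficients the result equals the input.
    """
    if calib is None:
        raise ValueError("undistortion requires a calibration profile")
    img = np.asarray(image)
    if not any(calib.dist_coeffs):
        return img.copy()
    h, w = img.shape[:2]
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ideal = np.stack([cc.ravel() + 0.0, rr.ravel() + 0.0], axis=1)
    src = distort_points(ideal, calib)
    coords = np.stack([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])

    def _remap(plane: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(plane.astype(float), coords, order=1, mode="constant")

    if img.ndim == 2:
        out = _remap(img)
    else:
        out = np.stack([_remap(img[..., ch]) for ch in range(img.shape[2])], axis=-1)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.rint(out), np.iinfo(img.dtype).min, np.iinfo(img.dtype).max)
    return out.astype(img.dtype)


# ---------------------------------------------------------------------------
# mask selection and cleanup
# ---------------------------------------------------------------------------

def extract_internode_mask(mask: LabeledMask) -> np.ndarray:
    """Boolean image, true where the class is 1 (cumulative internode)."""
    return mask.class_pixels(1)


def denoise_mask(binary: np.ndarray, min_component_px: int = 50,
                 opening_radius: int = 1, keep_largest: bool = True) -> np.ndarray:
    """Morphological opening + connected-component size filtering.

    Opens with a disk of ``opening_radius``, drops 8-connected components
    below ``min_component_px``, and (by default) keeps only the largest
    surviving component — one main stem per image — warning if more than
    one survived. Returns an all-false image when nothing survives.
    """
    binary = np.asarray(binary, dtype=bool)
    if opening_radius > 0:
        binary = morphology.opening(binary, morphology.disk(opening_radius))
    labels = skmeasure.label(binary, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(binary)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.flatnonzero(sizes >= min_component_px)
    if keep.size == 0:
        return np.zeros_like(binary)
    if keep_largest and keep.size > 1:
        warnings.warn(
            f"{keep.size} components survive denoising; keeping the largest",
            stacklevel=2,
        )
        keep = np.array([keep[np.argmax(sizes[keep])]])
    return np.isin(labels, keep)


# ---------------------------------------------------------------------------
# Zhang-Suen thinning
# ---------------------------------------------------------------------------

def _neighbors(p: np.ndarray) -> tuple[np.ndarray, ...]:
    """P2..P9 of the padded image, clockwise from north."""
    return (
        p[:-2, 1:-1],  # P2 N
        p[:-2, 2:],    # P3 NE
        p[1:-1, 2:],   # P4 E
        p[2:, 2:],     # P5 SE
        p[2:, 1:-1],   # P6 S
        p[2:, :-2],    # P7 SW
        p[1:-1, :-2],  # P8 W
        p[:-2, :-2],   # P9 NW
    )


def zhang_suen_thin(binary: np.ndarray) -> np.ndarray:
    """Classic two-subiteration Zhang-Suen thinning to a 1-px skeleton.

    Per pass a foreground pixel is deleted iff (a) it has 2..6 foreground
    neighbors, (b) the 8-neighborhood cycle P2..P9,P2 contains exactly one
    0->1 transition, and (c)/(d) the subiteration-specific N/E/S/W products
    vanish (pass 1: P2*P4*P6 = 0 and P4*P6*P8 = 0; pass 2: P2*P4*P8 = 0 and
    P2*P6*P8 = 0). Iterates until no pixel changes.
    """
    img = np.asarray(binary, dtype=bool).astype(np.uint8)
    if img.size == 0 or img.max() == 0:
        return img.astype(bool)

    while True:
        changed = False
        for step in (0, 1):
            p = np.pad(img, 1)
            nb = _neighbors(p)
            b = sum(n.astype(int) for n in nb)
            cycle = nb + (nb[0],)
            a = sum(
                ((cycle[i] == 0) & (cycle[i + 1] == 1)).astype(int)
                for i in range(8)
            )
            p2, _, p4, _, p6, _, p8, _ = nb
            if step == 0:
                cond = (p2 * p4 * p6 == 0) & (p4 * p6 * p8 == 0)
            else:
                cond = (p2 * p4 * p8 == 0) & (p2 * p6 * p8 == 0)
            delete = (img == 1) & (b >= 2) & (b <= 6) & (a == 1) & cond
            if delete.any():
                img[delete] = 0
                changed = True
        if not changed:
            break
    return img.astype(bool)


# ---------------------------------------------------------------------------
# skeleton ordering and arc length
# ---------------------------------------------------------------------------

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _bfs(start: tuple[int, int], pixset: set) -> tuple[dict, dict]:
    dist = {start: 0}
    parent: dict = {start: None}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        r, c = node
        for dr, dc in _OFFSETS:
            nxt = (r + dr, c + dc)
            if nxt in pixset and nxt not in dist:
                dist[nxt] = dist[node] + 1
                parent[nxt] = node
                queue.append(nxt)
    return dist, parent


def order_skeleton(skeleton: np.ndarray) -> SkeletonPath:
    """Extract the ordered centerline from a (possibly branched) skeleton.

    Endpoints are skeleton pixels with exactly one skeleton neighbor. The
    returned path is the longest geodesic between any two endpoints, which
    prunes short side spurs implicitly. Among disjoint components the
    largest is used (with a warning). A skeleton with no endpoints (a
    closed loop) raises :class:`SkeletonTopologyError`.
    """
    skel = np.asarray(skeleton, dtype=bool)
    if not skel.any():
        raise EmptyMaskError("empty skeleton")

    labels = skmeasure.label(skel, connectivity=2)
    if labels.max() > 1:
        warnings.warn(
            f"skeleton has {labels.max()} components; measuring the largest",
            stacklevel=2,
        )
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        skel = labels == np.argmax(sizes)

    pixels = list(map(tuple, np.argwhere(skel)))
    pixset = set(pixels)
    if len(pixels) == 1:
        return SkeletonPath(np.array(pixels))

    def degree(p):
        r, c = p
        return sum((r + dr, c + dc) in pixset for dr, dc in _OFFSETS)

    endpoints = [p for p in pixels if degree(p) == 1]
    if not endpoints:
        raise SkeletonTopologyError("skeleton is a closed loop (no endpoints)")

    # longest geodesic over all endpoint pairs
    best = (-1, None, None, None)  # (dist, start, end, parents)
    for ep in endpoints:
        dist, parent = _bfs(ep, pixset)
        far = max((d, p) for p, d in dist.items() if p in set(endpoints))
        if far[0] > best[0]:
            best = (far[0], ep, far[1], parent)

    _, start, end, parent = best
    path = [end]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path_arr = np.array(path[::-1])  # start -> end

    # orient basal-first: larger row index (lower in the image) leads
    if path_arr[-1, 0] > path_arr[0, 0]:
        path_arr = path_arr[::-1]
    return SkeletonPath(path_arr)


def arc_length_px(path: SkeletonPath) -> float:
    """Polyline arc length: sum of Euclidean steps along the ordered path.

    Axis-aligned steps contribute 1, diagonal steps sqrt(2); a single-pixel
    path has length 0.
    """
    px = path.pixels.astype(float)
    if len(px) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(px, axis=0).T)))


def length_mm(l_px: float, calib: CalibrationProfile) -> float:
    """Convert skeleton arc length to millimetres: L = k * L_px."""
    if calib.k <= 0:
        raise ValueError(f"longitudinal factor k must be positive, got {calib.k}")
    return calib.k * l_px


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def measure_seedling(mask: LabeledMask, calib: CalibrationProfile,
                     params: MeasureParams | None = None,
                     seedling_id: str = "", source: str = "") -> SeedlingResult:
    """Run the full chain on one class mask and return a graded result.

    An empty (or fully occluded) internode mask yields length 0, grade OUT
    and an ``empty_mask`` flag instead of an exception.
    """
    params = params or MeasureParams()
    flags: list[str] = []

    binary = extract_internode_mask(mask)
    clean = denoise_mask(binary, params.min_component_px, params.opening_radius)
    if not clean.any():
        return SeedlingResult(
            id=seedling_id, length_px=0.0, length_mm=0.0,
            grade="OUT", n_skeleton_px=0, source=source,
            flags=("empty_mask",),
        )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        skel = zhang_suen_thin(clean)
        path = order_skeleton(skel)
    flags.extend(str(w.message) for w in caught)

    l_px = arc_length_px(path)
    l_mm = length_mm(l_px, calib)
    return SeedlingResult(
        id=seedling_id,
        length_px=l_px,
        length_mm=l_mm,
        grade=grade(l_mm, params.bands),
        n_skeleton_px=len(path),
        source=source,
        flags=tuple(flags),
    )
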