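"""Reading and writing the external representations used by the pipeline.

Four currencies cross the package boundary:

* labelme polygon-annotation JSON (class labels 0 = branches/leaves,
  1 = cumulative-internode region, 2 = cotyledon node and below),
* integer class masks (single-channel PNG, background encoded as 255 so the
  class ids 0/1/2 match the annotation labels literally),
* a camera-calibration profile (intrinsics, Brown-Conrady distortion
  coefficients, and the longitudinal mm-per-pixel factor k),
* per-seedling measurement results (CSV).

Internally everything is 0-based (row, col); labelme stores points as
(x, y) = (col, row) and the conversion happens here, at the boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

BACKGROUND = 255
VALID_CLASSES = frozenset({0, 1, 2})

RESULT_COLUMNS = ["id", "length_px", "length_mm", "grade", "n_skeleton_px", "source"]


class AnnotationError(ValueError):
    """Raised for malformed or out-of-contract annotation input."""


@dataclass(frozen=True)
class PolygonAnnotation:
    """A labelme-style polygon annotation for one image.

    ``shapes`` is an ordered list of ``(label, points)`` pairs where
    ``points`` is an (n, 2) float array of (x, y) pixel coordinates.
    Order matters: later shapes overwrite earlier ones when rasterized.
    """

    image_path: str
    image_size: tuple[int, int]  # (height, width)
    shapes: tuple[tuple[int, np.ndarray], ...]

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise AnnotationError(f"non-positive image size {self.image_size}")
        for label, pts in self.shapes:
            if label not in VALID_CLASSES:
                raise AnnotationError(
                    f"label {label!r} outside the allowed classes {sorted(VALID_CLASSES)}"
                )
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
                raise AnnotationError("every polygon needs >= 3 (x, y) points")


@dataclass(frozen=True)
class LabeledMask:
    """Integer class image: values in {0, 1, 2} plus 255 for background."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        allowed = VALID_CLASSES | {BACKGROUND}
        extra = set(np.unique(arr)) - allowed
        if extra:
            raise ValueError(f"mask contains values outside {sorted(allowed)}: {sorted(extra)}")
        object.__setattr__(self, "data", arr.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def class_pixels(self, cls: int) -> np.ndarray:
        """Boolean image, true where the mask equals ``cls``."""
        return self.data == cls


@dataclass(frozen=True)
class CalibrationProfile:
    """Pinhole intrinsics + distortion + longitudinal scale.

    ``dist_coeffs`` follows the (k1, k2, p1, p2, k3) radial/tangential
    convention; ``k`` is the longitudinal factor in mm per pixel that
    converts skeleton arc length to physical length (L = k * L_px).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    dist_coeffs: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths fx, fy must be positive")
        if self.k <= 0:
            raise ValueError(f"longitudinal factor k must be positive, got {self.k}")
        coeffs = tuple(float(c) for c in self.dist_coeffs)
        if len(coeffs) < 5:
            coeffs = coeffs + (0.0,) * (5 - len(coeffs))
        object.__setattr__(self, "dist_coeffs", coeffs)

    @classmethod
    def identity(cls, k: float = 1.0) -> "CalibrationProfile":
        """A unit profile: no distortion, focal length 1, principal point 0."""
        return cls(fx=1.0, fy=1.0, cx=0.0, cy=0.0, k=k)

    def to_dict(self) -> dict:
        return {
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "dist": list(self.dist_coeffs),
            "k": self.k,
        }


@dataclass(frozen=True)
class SeedlingResult:
    """Outcome of measuring one seedling: pixel and mm length plus grade."""

    id: str
    length_px: float
    length_mm: float
    grade: str
    n_skeleton_px: int
    source: str = ""
    flags: tuple[str, ...] = field(default=())


def read_labelme(path: str | Path) -> PolygonAnnotation:
    """Parse a labelme JSON file into a :class:`PolygonAnnotation`.

    Labels are coerced to integers and must be one of {0, 1, 2}; points are
    clamped into the image bounds. Raises :class:`AnnotationError` for
    schema violations and ``json.JSONDecodeError`` for malformed JSON.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    try:
        h = int(doc["imageHeight"])
        w = int(doc["imageWidth"])
        raw_shapes = doc["shapes"]
    except KeyError as exc:
        raise AnnotationError(f"{path}: missing labelme key {exc}") from exc

    shapes: list[tuple[int, np.ndarray]] = []
    for shape in raw_shapes:
        try:
            label = int(str(shape["label"]))
        except ValueError as exc:
            raise AnnotationError(f"{path}: non-integer label {shape['label']!r}") from exc
        if label not in VALID_CLASSES:
            raise AnnotationError(
                f"{path}: label {label} outside the allowed classes {sorted(VALID_CLASSES)}"
            )
        pts = np.asarray(shape["points"], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise AnnotationError(f"{path}: polygon with < 3 points for label {label}")
        pts[:, 0] = np.clip(pts[:, 0], 0.0, w)
        pts[:, 1] = np.clip(pts[:, 1], 0.0, h)
        shapes.append((label, pts))

    return PolygonAnnotation(
        image_path=str(doc.get("imagePath", "")),
        image_size=(h, w),
        shapes=tuple(shapes),
    )


def _fill_polygon(target: np.ndarray, points_xy: np.ndarray, value: int) -> int:
    """Even-odd scanline fill at pixel centers (half-open rule).

    A pixel (r, c) is inside iff its center (c + 0.5, r + 0.5) lies inside
    the polygon; crossings are counted with the half-open edge rule
    (y1 <= y < y2), so shared edges between abutting polygons never double
    fill. Returns the number of pixels written.
    """
    h, w = target.shape
    xs = points_xy[:, 0]
    ys = points_xy[:, 1]
    x2 = np.roll(xs, -1)
    y2 = np.roll(ys, -1)

    r_lo = max(0, int(np.floor(ys.min() - 0.5)))
    r_hi = min(h - 1, int(np.ceil(ys.max())))
    written = 0
    for r in range(r_lo, r_hi + 1):
        yc = r + 0.5
        # edges straddling this scanline under the half-open rule
        straddle = ((ys <= yc) & (y2 > yc)) | ((y2 <= yc) & (ys > yc))
        if not straddle.any():
            continue
        t = (yc - ys[straddle]) / (y2[straddle] - ys[straddle])
        crossings = np.sort(xs[straddle] + t * (x2[straddle] - xs[straddle]))
        # even-odd: fill between consecutive crossing pairs
        for xa, xb in crossings.reshape(-1, 2):
            c_lo = max(0, int(np.ceil(xa - 0.5)))
            c_hi = min(w, int(np.ceil(xb - 0.5)))
            if c_hi > c_lo:
                target[r, c_lo:c_hi] = value
                written += c_hi - c_lo
    return written


def rasterize(ann: PolygonAnnotation) -> LabeledMask:
    """Rasterize polygon shapes to a class mask.

    Polygon interiors receive their class value; where shapes overlap the
    later shape wins (labelme stacking order). Zero-area polygons are
    skipped with a warning. Background is 255.
    """
    h, w = ann.image_size
    data = np.full((h, w), BACKGROUND, dtype=np.uint8)
    for label, pts in ann.shapes:
        # shoelace area; degenerate polygons contribute nothing
        x, y = pts[:, 0], pts[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area == 0.0:
            warnings.warn(f"skipping zero-area polygon with label {label}", stacklevel=2)
            continue
        _fill_polygon(data, pts, label)
    return LabeledMask(data)


def write_mask(mask: LabeledMask, path: str | Path) -> None:
    """Write a class mask as a single-channel 8-bit PNG."""
    Image.fromarray(mask.data, mode="L").save(Path(path))


def read_mask(path: str | Path) -> LabeledMask:
    """Read a single-channel PNG class mask."""
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return LabeledMask(arr)


def load_calibration(path: str | Path) -> CalibrationProfile:
    """Load a calibration profile from JSON or YAML.

    Expected keys: fx, fy, cx, cy, dist (list), k.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    missing = {"fx", "fy", "cx", "cy", "k"} - set(doc)
    if missing:
        raise ValueError(f"{path}: calibration config missing keys {sorted(missing)}")
    return CalibrationProfile(
        fx=float(doc["fx"]),
        fy=float(doc["fy"]),
        cx=float(doc["cx"]),
        cy=float(doc["cy"]),
        dist_coeffs=tuple(float(c) for c in doc.get("dist", [])),
        k=float(doc["k"]),
    )


def save_calibration(calib: CalibrationProfile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(calib.to_dict(), indent=2))


def write_results(results: Sequence[SeedlingResult], path: str | Path) -> int:
    """Write measurement results as CSV; returns the number of data rows."""
    frame = pd.DataFrame(
        [
            {
                "id": r.id,
                "length_px": r.length_px,
                "length_mm": r.length_mm,
                "grade": r.grade,
                "n_skeleton_px": r.n_skeleton_px,
                "source": r.source,
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )
    frame.to_csv(Path(path), index=False, float_format="%.6f")
    return len(frame)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back into a DataFrame (columns as written)."""
    return pd.read_csv(Path(path), keep_default_na=False)
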