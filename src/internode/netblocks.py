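"""Framework-free reference numerics for the three architectural blocks.

These are plain-NumPy forward implementations, built for unit-testable
correctness on small grids rather than speed, of:

* regular and deformable 2-D convolution (offset-displaced sampling with
  bilinear interpolation),
* the SIoU angle cost between a predicted and a ground-truth box,
* orthonormal Haar wavelet analysis/synthesis and the Haar-wavelet
  downsampling (HWD) block that re-encodes each 2x2 spatial block into four
  channel bands A/H/V/D.

Feature maps are float arrays of shape (channels, height, width); kernels
are (out_channels, in_channels, kh, kw). No gradients, no training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def n_sampling_positions(kh: int, kw: int) -> int:
    """Number of sampling positions N of a kh x kw kernel (N = kh*kw).

    The offset branch of a deformable convolution emits 2N channels:
    an (x, y) displacement per sampling position.
    """
    if kh < 1 or kw < 1:
        raise ValueError(f"kernel dims must be >= 1, got ({kh}, {kw})")
    return kh * kw


def _check_featuremap(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"feature map must be (C, H, W), got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


def _kernel_grid(kh: int, kw: int) -> tuple[np.ndarray, np.ndarray]:
    """Regular sampling offsets R, centered on the kernel origin."""
    rr = np.arange(kh) - (kh - 1) / 2
    cc = np.arange(kw) - (kw - 1) / 2
    gr, gc = np.meshgrid(rr, cc, indexing="ij")
    return gr.ravel(), gc.ravel()


def conv2d_regular(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Stride-1, same-size 2-D cross-correlation y(p0) = sum_n w(p_n) x(p0 + p_n).

    Zero padding preserves the spatial size. ``weights`` has shape
    (out_ch, in_ch, kh, kw) with in_ch matching the input channels.
    """
    x = _check_featuremap(x)
    w = np.asarray(weights, dtype=float)
    if w.ndim != 4:
        raise ValueError(f"kernel must be (O, C, kh, kw), got shape {w.shape}")
    out_ch, in_ch, kh, kw = w.shape
    if in_ch != x.shape[0]:
        raise ValueError(f"kernel expects {in_ch} input channels, feature map has {x.shape[0]}")

    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # windows: (C, H, W, kh, kw)
    return np.einsum("chwij,ocij->ohw", windows, w, optimize=True)


def _bilinear_sample(x: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinearly sample (C, H, W) at float (rows, cols); outside reads 0."""
    c, h, w = x.shape
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0

    out = np.zeros((c,) + rows.shape, dtype=float)
    for dr, dc, wt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        valid = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rs = np.clip(rr, 0, h - 1)
        cs = np.clip(cc, 0, w - 1)
        out += x[:, rs, cs] * (wt * valid)
    return out


def deform_conv2d(x: np.ndarray, weights: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Deformable convolution y(p0) = sum_n w(p_n) x(p0 + p_n + dp_n).

    ``offsets`` has shape (2N, H, W): channels (2n, 2n+1) hold the (row, col)
    displacement of sampling position n (row-major over the kernel grid).
    Fractional positions are resolved by bilinear interpolation; positions
    outside the input read as zero. With all-zero offsets this reduces
    exactly to :func:`conv2d_regular`.
    """
    x = _check_featuremap(x)
    w = np.asarray(weights, dtype=float)
    out_ch, in_ch, kh, kw = w.shape
    if in_ch != x.shape[0]:
        raise ValueError(f"kernel expects {in_ch} input channels, feature map has {x.shape[0]}")
    n = n_sampling_positions(kh, kw)
    off = np.asarray(offsets, dtype=float)
    _, h, wid = x.shape
    if off.shape != (2 * n, h, wid):
        raise ValueError(f"offset field must have shape {(2 * n, h, wid)}, got {off.shape}")

    gr, gc = _kernel_grid(kh, kw)
    base_r, base_c = np.meshgrid(np.arange(h), np.arange(wid), indexing="ij")
    wflat = w.reshape(out_ch, in_ch, n)

    out = np.zeros((out_ch, h, wid), dtype=float)
    for i in range(n):
        rows = base_r + gr[i] + off[2 * i]
        cols = base_c + gc[i] + off[2 * i + 1]
        sampled = _bilinear_sample(x, rows, cols)  # (C, H, W)
        out += np.einsum("chw,oc->ohw", sampled, wflat[:, :, i], optimize=True)
    return out


# ---------------------------------------------------------------------------
# SIoU angle cost
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxPair:
    """A predicted and a ground-truth axis-aligned box, each (cx, cy, w, h).

    Derived quantities: ``c_h`` the vertical center distance, ``sigma`` the
    Euclidean center distance, and the center-line angle alpha with
    sin(alpha) = c_h / sigma.
    """

    pred: tuple[float, float, float, float]
    gt: tuple[float, float, float, float]

    @property
    def c_h(self) -> float:
        return abs(self.pred[1] - self.gt[1])

    @property
    def c_w(self) -> float:
        return abs(self.pred[0] - self.gt[0])

    @property
    def sigma(self) -> float:
        return math.hypot(self.c_w, self.c_h)


def siou_angle_cost(pair: BoxPair) -> float:
    """SIoU angle penalty Lambda = 1 - 2 sin^2(arcsin(c_h / sigma) - pi/4).

    Vanishes when the center line is axis-aligned (alpha = 0 or 90 degrees)
    and peaks at 1 when alpha = 45 degrees, steering box regression toward
    axis alignment. Coincident centers (sigma = 0) are defined to carry no
    angular penalty (Lambda = 0).
    """
    sigma = pair.sigma
    if sigma == 0.0:
        return 0.0
    ratio = min(1.0, max(0.0, pair.c_h / sigma))  # clamp against float error
    return 1.0 - 2.0 * math.sin(math.asin(ratio) - math.pi / 4.0) ** 2


def siou_loss(pair: BoxPair, theta: float = 4.0) -> float:
    """Full SIoU box loss: 1 - IoU + (distance + shape costs) / 2.

    Composite around :func:`siou_angle_cost`: the distance cost is damped by
    gamma = 2 - Lambda, the shape cost uses exponent ``theta``. Provided as
    an optional whole; the angle cost alone is the tested contract.
    """
    lam = siou_angle_cost(pair)
    (pcx, pcy, pw, ph), (gcx, gcy, gw, gh) = pair.pred, pair.gt

    # enclosing box
    px1, px2 = pcx - pw / 2, pcx + pw / 2
    py1, py2 = pcy - ph / 2, pcy + ph / 2
    gx1, gx2 = gcx - gw / 2, gcx + gw / 2
    gy1, gy2 = gcy - gh / 2, gcy + gh / 2
    cw = max(px2, gx2) - min(px1, gx1)
    ch = max(py2, gy2) - min(py1, gy1)

    inter = max(0.0, min(px2, gx2) - max(px1, gx1)) * max(0.0, min(py2, gy2) - max(py1, gy1))
    union = pw * ph + gw * gh - inter
    iou = inter / union if union > 0 else 0.0

    gamma = 2.0 - lam
    rho_x = ((gcx - pcx) / cw) ** 2 if cw > 0 else 0.0
    rho_y = ((gcy - pcy) / ch) ** 2 if ch > 0 else 0.0
    dist = (1 - math.exp(-gamma * rho_x)) + (1 - math.exp(-gamma * rho_y))

    ww = abs(pw - gw) / max(pw, gw) if max(pw, gw) > 0 else 0.0
    wh = abs(ph - gh) / max(ph, gh) if max(ph, gh) > 0 else 0.0
    shape = (1 - math.exp(-ww)) ** theta + (1 - math.exp(-wh)) ** theta

    return 1.0 - iou + (dist + shape) / 2.0


# ---------------------------------------------------------------------------
# Haar wavelet downsampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveletBands:
    """Single-level 2-D Haar bands, each (C, h/2, w/2).

    A = approximation, H = horizontal detail (variation along columns),
    V = vertical detail (variation along rows), D = diagonal detail.
    ``pad`` records whether the source was reflect-padded to even size.
    """

    A: np.ndarray
    H: np.ndarray
    V: np.ndarray
    D: np.ndarray
    pad: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        shapes = {self.A.shape, self.H.shape, self.V.shape, self.D.shape}
        if len(shapes) != 1:
            raise ValueError(f"bands must share one shape, got {shapes}")


def haar_dwt2(x: np.ndarray) -> WaveletBands:
    """Orthonormal single-level 2-D Haar transform per 2x2 block.

    For each non-overlapping block [[a, b], [c, d]]:
    A = (a+b+c+d)/2, H = (a-b+c-d)/2, V = (a+b-c-d)/2, D = (a-b-c+d)/2.
    The 1/2 factor makes the transform orthonormal, so energy is conserved
    exactly (Parseval). Odd spatial sizes are reflect-padded by one row or
    column, recorded in the result's ``pad``.
    """
    x = _check_featuremap(x)
    if x.shape[1] == 0 or x.shape[2] == 0:
        raise ValueError("empty feature map")
    pad_h = x.shape[1] % 2
    pad_w = x.shape[2] % 2
    if pad_h or pad_w:
        x = np.pad(x, ((0, 0), (0, pad_h), (0, pad_w)), mode="reflect")

    a = x[:, 0::2, 0::2]
    b = x[:, 0::2, 1::2]
    c = x[:, 1::2, 0::2]
    d = x[:, 1::2, 1::2]
    return WaveletBands(
        A=(a + b + c + d) / 2.0,
        H=(a - b + c - d) / 2.0,
        V=(a + b - c - d) / 2.0,
        D=(a - b - c + d) / 2.0,
        pad=(pad_h, pad_w),
    )


def haar_idwt2(bands: WaveletBands) -> np.ndarray:
    """Exact inverse of :func:`haar_dwt2` (padding removed if recorded)."""
    A, H, V, D = bands.A, bands.H, bands.V, bands.D
    c_, h2, w2 = A.shape
    out = np.empty((c_, 2 * h2, 2 * w2), dtype=float)
    out[:, 0::2, 0::2] = (A + H + V + D) / 2.0
    out[:, 0::2, 1::2] = (A - H + V - D) / 2.0
    out[:, 1::2, 0::2] = (A + H - V - D) / 2.0
    out[:, 1::2, 1::2] = (A - H - V + D) / 2.0
    ph, pw = bands.pad
    if ph or pw:
        out = out[:, : out.shape[1] - ph, : out.shape[2] - pw]
    return out


def hwd_downsample(x: np.ndarray) -> np.ndarray:
    """Haar-wavelet downsampling: (C, h, w) -> (4C, h/2, w/2).

    Concatenates the A, H, V, D bands along the channel axis, trading
    spatial resolution for channels without discarding information: unlike
    max pooling, weak one-pixel edges survive in the detail bands and the
    input is exactly recoverable via :func:`hwd_unpack`.
    """
    bands = haar_dwt2(x)
    return np.concatenate([bands.A, bands.H, bands.V, bands.D], axis=0)


def hwd_unpack(y: np.ndarray, pad: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Invert :func:`hwd_downsample`: (4C, h/2, w/2) -> (C, h, w)."""
    y = _check_featuremap(y)
    if y.shape[0] % 4:
        raise ValueError("channel count must be a multiple of 4")
    c = y.shape[0] // 4
    bands = WaveletBands(A=y[:c], H=y[c : 2 * c], V=y[2 * c : 3 * c], D=y[3 * c :], pad=pad)
    return haar_idwt2(bands)


def maxpool2x2(x: np.ndarray) -> np.ndarray:
    """Plain 2x2 max pooling, for contrast with :func:`hwd_downsample`."""
    x = _check_featuremap(x)
    if x.shape[1] % 2 or x.shape[2] % 2:
        raise ValueError("maxpool2x2 needs even spatial dims")
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).max(axis=(2, 4))
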