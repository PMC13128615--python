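"""Photometric/geometric augmentation policy and dataset expansion.

The policy mirrors a conservative field-imaging regime: brightness jitter of
at most +-20% (lighting changes), additive Gaussian noise with sigma in
[5, 25] intensity units (sensor noise), 3x3 Gaussian blur with sigma in
[0.1, 2.0] (focus error), and horizontal flip. Expanding a dataset keeps
every original and adds two augmented copies per image, each copy produced
by composing two distinct randomly chosen techniques, so the dataset
triples (1,100 images -> 3,300 samples).

Photometric ops leave the annotation mask untouched; ops that move pixels
(the flip) transform image and mask jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class AugmentPolicy:
    brightness_limit: float = 0.20
    noise_sigma_range: tuple[float, float] = (5.0, 25.0)
    blur_kernel: int = 3
    blur_sigma_range: tuple[float, float] = (0.1, 2.0)
    techniques_per_image: int = 2
    copies_per_image: int = 2
    techniques: tuple[str, ...] = field(
        default=("brightness", "noise", "blur", "hflip")
    )

    def __post_init__(self) -> None:
        if self.techniques_per_image > len(self.techniques):
            raise ValueError(
                f"cannot pick {self.techniques_per_image} of {len(self.techniques)} techniques"
            )
        unknown = set(self.techniques) - set(_TECHNIQUES)
        if unknown:
            raise ValueError(f"unknown techniques {sorted(unknown)}")


def _check_8bit(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError(f"expected an 8-bit image, got dtype {img.dtype}")
    return img


def random_brightness(image: np.ndarray, factor: float,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Scale every pixel by (1 + factor), factor in [-0.2, 0.2], clip to [0, 255]."""
    img = _check_8bit(image)
    if not -0.2 <= factor <= 0.2:
        raise ValueError(f"brightness factor must be in [-0.2, 0.2], got {factor}")
    out = np.rint(img.astype(float) * (1.0 + factor))
    return np.clip(out, 0, 255).astype(np.uint8)


def gauss_noise(image: np.ndarray, sigma: float,
                rng: np.random.Generator) -> np.ndarray:
    """Additive zero-mean Gaussian noise, sigma in [5, 25], clipped to [0, 255]."""
    img = _check_8bit(image)
    if not 5.0 <= sigma <= 25.0:
        raise ValueError(f"noise sigma must be in [5, 25], got {sigma}")
    out = np.rint(img.astype(float) + rng.normal(0.0, sigma, size=img.shape))
    return np.clip(out, 0, 255).astype(np.uint8)


def gaussian_kernel_3x3(sigma: float) -> np.ndarray:
    """3x3 Gaussian kernel sampled at integer offsets, normalized to sum 1."""
    g = np.exp(-np.arange(-1, 2) ** 2 / (2.0 * sigma**2))
    kern = np.outer(g, g)
    return kern / kern.sum()


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """3x3 Gaussian blur, sigma in [0.1, 2.0], reflect-padded borders."""
    img = _check_8bit(image)
    if not 0.1 <= sigma <= 2.0:
        raise ValueError(f"blur sigma must be in [0.1, 2.0], got {sigma}")
    kern = gaussian_kernel_3x3(sigma)
    flt = img.astype(float)
    if flt.ndim == 3:
        out = np.stack(
            [ndimage.correlate(flt[..., c], kern, mode="reflect") for c in range(flt.shape[2])],
            axis=-1,
        )
    else:
        out = ndimage.correlate(flt, kern, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def hflip(image: np.ndarray) -> np.ndarray:
    """Mirror along the vertical axis (columns reversed)."""
    return np.asarray(image)[:, ::-1].copy()


def _apply_brightness(image, mask, rng, policy):
    f = rng.uniform(-policy.brightness_limit, policy.brightness_limit)
    return random_brightness(image, f), mask


def _apply_noise(image, mask, rng, policy):
    s = rng.uniform(*policy.noise_sigma_range)
    return gauss_noise(image, s, rng), mask


def _apply_blur(image, mask, rng, policy):
    s = rng.uniform(*policy.blur_sigma_range)
    return gaussian_blur(image, s), mask


def _apply_hflip(image, mask, rng, policy):
    return hflip(image), (None if mask is None else hflip(mask))


_TECHNIQUES = {
    "brightness": _apply_brightness,
    "noise": _apply_noise,
    "blur": _apply_blur,
    "hflip": _apply_hflip,
}


def augment_once(image: np.ndarray, mask: np.ndarray | None,
                 names, rng: np.random.Generator,
                 policy: AugmentPolicy) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply the named techniques in sequence to one (image, mask) pair."""
    for name in names:
        image, mask = _TECHNIQUES[name](image, mask, rng, policy)
    return image, mask


def expand_dataset(images, policy: AugmentPolicy | None = None,
                   rng_seed: int = 0, masks=None):
    """Originals + ``copies_per_image`` augmented copies per original.

    Each copy composes ``techniques_per_image`` distinct techniques chosen
    at random. Returns ``(images_out, masks_out, recipe)`` where ``recipe``
    lists the technique names used per output and ``masks_out`` is None when
    no masks were given. |images_out| = |images| * (1 + copies_per_image).
    """
    policy = policy or AugmentPolicy()
    rng = np.random.default_rng(rng_seed)
    if masks is not None and len(masks) != len(images):
        raise ValueError("masks misaligned with images")

    images_out: list[np.ndarray] = []
    masks_out: list = []
    recipe: list[tuple[str, ...]] = []
    for i, img in enumerate(images):
        msk = None if masks is None else masks[i]
        images_out.append(np.asarray(img))
        masks_out.append(msk)
        recipe.append(("original",))
        for _ in range(policy.copies_per_image):
            names = tuple(
                rng.choice(policy.techniques, size=policy.techniques_per_image,
                           replace=False)
            )
            aug_img, aug_msk = augment_once(img, msk, names, rng, policy)
            images_out.append(aug_img)
            masks_out.append(aug_msk)
            recipe.append(names)
    return images_out, (None if masks is None else masks_out), recipe
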