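"""MRI noise injection at a target SNR and the data-augmentation suite.

Noise follows the magnitude-MRI convention: SNR is the mean foreground
signal divided by the noise standard deviation.  Gaussian noise is additive;
Rician noise re-magnitudes the signal with two independent Gaussian channels
(sqrt((I+n1)^2 + n2^2)); Rayleigh noise is an additive, mean-centred
Rayleigh draw whose sd matches the target sigma; the mixed scenario picks
one of the three per image at random.

Augmentation mirrors a standard cine-MRI training recipe: elastic
deformation, in-plane shifts, rotation (-20..20 deg), scaling, Gaussian blur
(sigma in [0.5, 1.5]) and gamma correction (gamma ~ N(1, 0.1)); a dataset is
inflated by a factor of ten by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import MaskStack

__all__ = ["NoiseSpec", "AugmentationSpec", "add_noise", "augment_one",
           "inflate_dataset", "TRANSFORMS"]

TRANSFORMS = ("elastic", "shift", "rotation", "scaling", "blur", "gamma")


@dataclass
class NoiseSpec:
    """Which noise distribution to apply and at what SNR."""

    distribution: Literal["gaussian", "rician", "rayleigh", "mixed"] = "gaussian"
    snr: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.distribution not in ("gaussian", "rician", "rayleigh", "mixed"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass
class AugmentationSpec:
    """Ranges for the six augmentation transforms and the inflation factor.

    ``transforms`` limits which transforms may be drawn; by default a
    non-empty random subset of all six is applied per augmentation.
    """

    rotation_deg: tuple[float, float] = (-20.0, 20.0)
    shift_frac: tuple[float, float] = (-0.1, 0.1)      # of in-plane extent, x and y
    scale: tuple[float, float] = (0.9, 1.1)
    blur_sigma: tuple[float, float] = (0.5, 1.5)
    gamma_mean_sd: tuple[float, float] = (1.0, 0.1)
    elastic_amplitude_vox: float = 8.0
    elastic_smoothing_vox: float = 4.0
    inflation_factor: int = 10
    transforms: tuple[str, ...] = TRANSFORMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inflation_factor < 1:
            raise ValueError("inflation_factor must be >= 1")
        if self.blur_sigma[0] <= 0:
            raise ValueError("blur sigma must be positive")
        unknown = set(self.transforms) - set(TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown transforms {sorted(unknown)}")
        if not self.transforms:
            raise ValueError("at least one transform must be enabled")


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def _sigma_from_snr(image: np.ndarray, fg_mask: Optional[MaskStack], snr: float) -> float:
    region = image if fg_mask is None else image[fg_mask.voxels.astype(bool)]
    mu = float(np.mean(region))
    sigma = mu / snr
    if sigma <= 0:
        raise ValueError(f"non-positive noise sigma ({sigma:g}); "
                         "mean signal must be positive")
    return sigma


def add_noise(image: np.ndarray, fg_mask: Optional[MaskStack],
              spec: NoiseSpec) -> np.ndarray:
    """Corrupt an intensity volume with noise at the spec's SNR.

    sigma = mean foreground intensity / snr (whole-image mean if no mask).
    """
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(spec.seed)
    dist = spec.distribution
    if dist == "mixed":
        dist = rng.choice(["gaussian", "rician", "rayleigh"])
    if dist == "rician" and image.min() < 0:
        raise ValueError("Rician noise requires non-negative intensities")
    sigma = _sigma_from_snr(image, fg_mask, spec.snr)

    if dist == "gaussian":
        return image + rng.normal(0.0, sigma, image.shape)
    if dist == "rician":
        n1 = rng.normal(0.0, sigma, image.shape)
        n2 = rng.normal(0.0, sigma, image.shape)
        return np.sqrt((image + n1) ** 2 + n2 ** 2)
    # rayleigh: additive, mean-centred, sd matched to sigma
    scale = sigma / np.sqrt((4.0 - np.pi) / 2.0)
    r = rng.rayleigh(scale, image.shape)
    return image + (r - scale * np.sqrt(np.pi / 2.0))


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _warp_inplane(vol: np.ndarray, matrix: np.ndarray, offset: np.ndarray,
                  order: int) -> np.ndarray:
    """Apply a 2D affine (y, x) slice-wise to a (z, y, x) volume."""
    out = np.empty_like(vol, dtype=float)
    for z in range(vol.shape[0]):
        out[z] = ndimage.affine_transform(vol[z], matrix, offset=offset,
                                          order=order, mode="constant", cval=vol.min())
    return out


def _elastic_fields(shape_yx: tuple[int, int], amplitude: float, smoothing: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, shape_yx), smoothing) * amplitude
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, shape_yx), smoothing) * amplitude
    return dy, dx


def augment_one(image: np.ndarray, mask: MaskStack, spec: AugmentationSpec,
                rng: np.random.Generator | int | None = None,
                ) -> tuple[np.ndarray, MaskStack]:
    """Apply a random non-empty subset of the enabled transforms.

    Geometric transforms (elastic, shift, rotation, scaling) act identically
    on image (trilinear) and mask (nearest, re-binarised) and are in-plane
    only; blur and gamma touch the image alone.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != mask.voxels.shape:
        raise ValueError("image and mask must share a shape")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(spec.seed if rng is None else rng)

    enabled = list(spec.transforms)
    chosen = {t for t in enabled if rng.random() < 0.5}
    if not chosen:
        chosen = {enabled[int(rng.integers(len(enabled)))]}

    img = image.copy()
    msk = mask.voxels.astype(float)
    H, W = img.shape[1], img.shape[2]

    if "elastic" in chosen:
        dy, dx = _elastic_fields((H, W), spec.elastic_amplitude_vox,
                                 spec.elastic_smoothing_vox, rng)
        yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        coords = np.stack([yy + dy, xx + dx])
        for z in range(img.shape[0]):
            img[z] = ndimage.map_coordinates(img[z], coords, order=1,
                                             mode="constant", cval=img.min())
            msk[z] = ndimage.map_coordinates(msk[z], coords, order=0,
                                             mode="constant", cval=0.0)

    # compose shift / rotation / scaling into a single in-plane affine
    theta = np.deg2rad(rng.uniform(*spec.rotation_deg)) if "rotation" in chosen else 0.0
    s = rng.uniform(*spec.scale) if "scaling" in chosen else 1.0
    if "shift" in chosen:
        ty = rng.uniform(*spec.shift_frac) * H
        tx = rng.uniform(*spec.shift_frac) * W
    else:
        ty = tx = 0.0
    if theta != 0.0 or s != 1.0 or ty != 0.0 or tx != 0.0:
        c = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
        t = np.array([ty, tx])
        # output -> input mapping: undo translation, then rotation/scale about centre
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]]) / s
        offset = c - rot @ (c + t)
        img = _warp_inplane(img, rot, offset, order=1)
        msk = _warp_inplane(msk, rot, offset, order=0)

    if "blur" in chosen:
        sig = rng.uniform(*spec.blur_sigma)
        img = ndimage.gaussian_filter(img, sigma=(0.0, sig, sig))

    if "gamma" in chosen:
        g = rng.normal(*spec.gamma_mean_sd)
        g = max(g, 0.1)
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = ((img - lo) / (hi - lo)) ** g * (hi - lo) + lo

    out_mask = MaskStack((msk > 0.5).astype(np.uint8), mask.spacing_mm, mask.label)
    return img, out_mask


def inflate_dataset(pairs: Sequence[tuple[np.ndarray, MaskStack]],
                    spec: AugmentationSpec,
                    ) -> list[tuple[np.ndarray, MaskStack]]:
    """Inflate (image, mask) pairs by the spec's factor.

    Returns the originals followed by ``factor - 1`` seeded augmentations of
    each pair; deterministic for a fixed ``spec.seed``.
    """
    if not pairs:
        raise ValueError("empty input")
    out = list(pairs)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(pairs) * max(spec.inflation_factor - 1, 0))
    k = 0
    for img, msk in pairs:
        for _ in range(spec.inflation_factor - 1):
            rng = np.random.default_rng(children[k]); k += 1
            out.append(augment_one(img, msk, spec, rng))
    return out
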