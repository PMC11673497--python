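"""Training-pair preprocessing: normalization, augmentation, patch extraction.

Augmentation draws one geometric transform (a quarter-turn rotation plus
optional flips — quarter-turns only, so no resampling artifacts and LR/HR
stay exactly aligned) and one photometric jitter (additive brightness,
multiplicative contrast about the image mean) per call.  Geometric and
photometric transforms are applied consistently to both images of a
pair; acquisition-style noise/blur is applied to the LR image only by
default (flag to apply to both).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ContractError


def normalize(img: np.ndarray, value_range: str = "auto") -> np.ndarray:
    """Map an image to float32 in [0, 1].

    ``value_range`` is '0-255' (8-bit), '0-1', or 'auto' (integer dtypes
    are treated as 8-bit, floats as already normalised).
    """
    arr = np.asarray(img)
    if value_range == "auto":
        value_range = "0-255" if np.issubdtype(arr.dtype, np.integer) else "0-1"
    if value_range == "0-255":
        return (arr.astype(np.float32) / 255.0).clip(0.0, 1.0)
    if value_range == "0-1":
        return arr.astype(np.float32).clip(0.0, 1.0)
    raise ContractError(f"unknown value_range {value_range!r}")


def denormalize(img: np.ndarray, value_range: str = "0-255") -> np.ndarray:
    """Inverse of :func:`normalize`; exact on integer round-trips."""
    arr = np.asarray(img, dtype=np.float32).clip(0.0, 1.0)
    if value_range == "0-255":
        return np.round(arr * 255.0).astype(np.uint8)
    if value_range == "0-1":
        return arr
    raise ContractError(f"unknown value_range {value_range!r}")


@dataclass
class AugmentSpec:
    """One augmentation policy (all draws come from ``seed``)."""

    rotations: tuple[int, ...] = (0, 90, 180, 270)
    hflip: bool = True
    vflip: bool = True
    brightness_delta: float = 0.0  # max |additive shift|
    contrast_range: tuple[float, float] = (1.0, 1.0)  # multiplicative, about the mean
    gauss_noise_sigma: float = 0.0
    gauss_blur_sigma: float = 0.0
    noise_on: str = "lr"  # 'lr' (acquisition-style) or 'both'
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.rotations) - {0, 90, 180, 270}
        if bad:
            raise ContractError(f"rotations must be quarter-turns, got {bad}")
        if self.noise_on not in ("lr", "both"):
            raise ContractError("noise_on must be 'lr' or 'both'")


def _geometric(img: np.ndarray, k: int, hflip: bool, vflip: bool) -> np.ndarray:
    out = np.rot90(img, k)
    if hflip:
        out = out[:, ::-1]
    if vflip:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment_pair(
    lr: np.ndarray, hr: np.ndarray, spec: AugmentSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one augmentation from spec's RNG and apply it to the pair."""
    if hr.shape[0] % lr.shape[0] or hr.shape[1] % lr.shape[1] or (
        hr.shape[0] // lr.shape[0] != hr.shape[1] // lr.shape[1]
    ):
        raise ContractError(
            f"misaligned pair: LR {lr.shape} vs HR {hr.shape}"
        )
    rng = np.random.default_rng(spec.seed)
    k = int(rng.choice(np.asarray(spec.rotations))) // 90
    do_h = bool(spec.hflip and rng.integers(2))
    do_v = bool(spec.vflip and rng.integers(2))
    lr_out = _geometric(lr, k, do_h, do_v).astype(np.float32)
    hr_out = _geometric(hr, k, do_h, do_v).astype(np.float32)

    delta = float(rng.uniform(-spec.brightness_delta, spec.brightness_delta))
    lo, hi = spec.contrast_range
    factor = float(rng.uniform(lo, hi))
    for img in (lr_out, hr_out):
        if factor != 1.0:
            mean = img.mean()
            img *= factor
            img += (1.0 - factor) * mean
        if delta:
            img += delta

    if spec.gauss_blur_sigma > 0:
        lr_out = gaussian_filter(lr_out, spec.gauss_blur_sigma)
        if spec.noise_on == "both":
            hr_out = gaussian_filter(hr_out, spec.gauss_blur_sigma)
    if spec.gauss_noise_sigma > 0:
        lr_out = lr_out + rng.normal(0, spec.gauss_noise_sigma, lr_out.shape).astype(np.float32)
        if spec.noise_on == "both":
            hr_out = hr_out + rng.normal(0, spec.gauss_noise_sigma, hr_out.shape).astype(np.float32)

    return np.clip(lr_out, 0.0, 1.0), np.clip(hr_out, 0.0, 1.0)


def extract_patches(
    lr: np.ndarray,
    hr: np.ndarray,
    patch: int,
    n: int,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """n random aligned patch pairs: LR patch x patch, HR at scale x the
    same offset."""
    scale = hr.shape[0] // lr.shape[0]
    if hr.shape != (lr.shape[0] * scale, lr.shape[1] * scale):
        raise ContractError(f"misaligned pair: LR {lr.shape} vs HR {hr.shape}")
    if patch > min(lr.shape):
        raise ContractError(
            f"patch {patch} larger than LR dims {lr.shape}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        y = int(rng.integers(0, lr.shape[0] - patch + 1))
        x = int(rng.integers(0, lr.shape[1] - patch + 1))
        lp = lr[y : y + patch, x : x + patch]
        hp = hr[y * scale : (y + patch) * scale, x * scale : (x + patch) * scale]
        out.append((np.ascontiguousarray(lp), np.ascontiguousarray(hp)))
    return out
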