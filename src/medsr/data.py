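"""Synthetic phantom images, the HR->LR degradation pipeline, and image I/O.

Two phantom families stand in for acquired scans (both synthetic by
construction, values in [0, 1], bitwise reproducible per seed):

* ``ct_mri_like`` (default 512 x 512): a bright outer rim, an inner
  tissue disc and a set of randomly placed, rotated ellipses of distinct
  intensity on a dark background, plus a smooth multiplicative bias
  field and slight edge smoothing — piecewise-smooth tomography-style
  anatomy.
* ``ultrasound_like`` (default 256 x 256): low-frequency anatomy
  modulated by a Rayleigh-envelope speckle texture with a few bright
  ellipsoidal inclusions — kidney-stone-style sonography texture.

Degradation maps HR to LR: optional Gaussian blur, bicubic downsampling
by the scale factor, optional additive Gaussian noise, clip to [0, 1].
Bicubic resampling (up and down) goes through Pillow, which antialiases
on reduction — the field's conventional bicubic pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as PILImage
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, ContractError


# -- phantom generation --------------------------------------------------


@dataclass
class PhantomSpec:
    """Recipe for one synthetic image family."""

    modality: str = "ct_mri_like"  # or "ultrasound_like"
    size: int | None = None  # default 512 CT/MRI-like, 256 ultrasound-like
    n_ellipses: int = 8
    speckle_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("ct_mri_like", "ultrasound_like"):
            raise ConfigError(f"unknown modality {self.modality!r}")
        if self.size is None:
            self.size = 512 if self.modality == "ct_mri_like" else 256
        if self.size < 64:
            raise ConfigError("size must be >= 64")
        if self.size % 4:
            raise ConfigError("size must be divisible by 4 so both scales apply")


def _ellipse_mask(size: int, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y = (yy - cy) / size
    x = (xx - cx) / size
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _ct_mri_like(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.size
    img = np.zeros((n, n), dtype=np.float64)
    # outer rim (skull-like) and inner tissue disc
    img[_ellipse_mask(n, n / 2, n / 2, 0.46, 0.40, 0.0)] = 0.95
    img[_ellipse_mask(n, n / 2, n / 2, 0.42, 0.36, 0.0)] = 0.35
    for _ in range(spec.n_ellipses):
        cy = rng.uniform(0.30 * n, 0.70 * n)
        cx = rng.uniform(0.30 * n, 0.70 * n)
        ry = rng.uniform(0.02, 0.12)
        rx = rng.uniform(0.02, 0.12)
        theta = rng.uniform(0.0, np.pi)
        level = rng.uniform(0.1, 0.9)
        img[_ellipse_mask(n, cy, cx, ry, rx, theta)] = level
    # smooth multiplicative bias field, as in real tomographic recon
    bias = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 8)
    bias = 1.0 + 0.15 * bias / (np.abs(bias).max() + 1e-12)
    img = img * bias
    img = gaussian_filter(img, sigma=0.7)  # soften binary edges slightly
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def _ultrasound_like(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.size
    anatomy = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 10)
    anatomy = 0.25 + 0.5 * (anatomy - anatomy.min()) / (np.ptp(anatomy) + 1e-12)
    # fully developed speckle: Rayleigh envelope of a filtered complex field
    re = gaussian_filter(rng.standard_normal((n, n)), sigma=1.0)
    im = gaussian_filter(rng.standard_normal((n, n)), sigma=1.0)
    envelope = np.hypot(re, im)
    envelope /= envelope.mean() + 1e-12
    w = spec.speckle_strength
    img = anatomy * ((1.0 - w) + w * envelope)
    # bright inclusions (stones)
    for _ in range(max(1, spec.n_ellipses // 3)):
        cy = rng.uniform(0.25 * n, 0.75 * n)
        cx = rng.uniform(0.25 * n, 0.75 * n)
        r = rng.uniform(0.015, 0.05)
        mask = _ellipse_mask(n, cy, cx, r, r * rng.uniform(0.7, 1.4), rng.uniform(0, np.pi))
        img[mask] = np.clip(img[mask] + rng.uniform(0.35, 0.6), 0.0, 1.0)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom; deterministic per (spec, seed), values in [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    if spec.modality == "ct_mri_like":
        return _ct_mri_like(spec, rng)
    return _ultrasound_like(spec, rng)


# -- bicubic resampling and degradation ----------------------------------


def _pil_resize(img: np.ndarray, size_hw: tuple[int, int]) -> np.ndarray:
    pil = PILImage.fromarray(np.asarray(img, dtype=np.float32), mode="F")
    out = pil.resize((size_hw[1], size_hw[0]), resample=PILImage.Resampling.BICUBIC)
    return np.asarray(out, dtype=np.float32)


def bicubic_upscale(lr: np.ndarray, scale: int) -> np.ndarray:
    """Zero-parameter bicubic baseline: resize to scale-times dimensions."""
    if scale not in (2, 4):
        raise ContractError(f"scale must be 2 or 4, got {scale}")
    h, w = lr.shape
    return np.clip(_pil_resize(lr, (h * scale, w * scale)), 0.0, 1.0)


def bicubic_downscale(hr: np.ndarray, scale: int) -> np.ndarray:
    h, w = hr.shape
    if h % scale or w % scale:
        raise ContractError(
            f"HR dims {hr.shape} not divisible by scale {scale}"
        )
    return _pil_resize(hr, (h // scale, w // scale))


@dataclass
class DegradationSpec:
    """HR -> LR forward process: blur, bicubic downsample, additive noise."""

    scale: int = 2
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    downsample_kernel: str = "bicubic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale not in (2, 4):
            raise ConfigError(f"scale must be 2 or 4, got {self.scale}")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ConfigError("blur_sigma and noise_sigma must be >= 0")
        if self.downsample_kernel != "bicubic":
            raise ConfigError("only bicubic downsampling is supported")


def degrade(hr: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Apply the degradation pipeline; deterministic per spec.seed."""
    hr = np.asarray(hr, dtype=np.float32)
    if hr.shape[0] % spec.scale or hr.shape[1] % spec.scale:
        raise ContractError(
            f"HR dims {hr.shape} not divisible by scale {spec.scale}"
        )
    img = hr
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, sigma=spec.blur_sigma)
    img = bicubic_downscale(img, spec.scale)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


# -- paired dataset ------------------------------------------------------


@dataclass
class SRDataset:
    """Matched LR/HR pairs with a deterministic train/val/test split."""

    hr: list[np.ndarray]
    lr: list[np.ndarray]
    scale: int
    train_idx: list[int]
    val_idx: list[int]
    test_idx: list[int]

    def __len__(self) -> int:
        return len(self.hr)

    def pairs(self, split: str) -> list[tuple[np.ndarray, np.ndarray]]:
        idx = {"train": self.train_idx, "val": self.val_idx, "test": self.test_idx}[split]
        return [(self.lr[i], self.hr[i]) for i in idx]


def split_indices(n: int) -> tuple[list[int], list[int], list[int]]:
    """Deterministic 80/10/10 split by index: the last ceil(n/10) images
    are the test set, the ceil(n/10) before them validation, the rest
    training (each split non-empty for n >= 3)."""
    n_test = max(1, int(np.ceil(n / 10))) if n >= 3 else 0
    n_val = n_test
    n_train = n - n_val - n_test
    train = list(range(n_train))
    val = list(range(n_train, n_train + n_val))
    test = list(range(n_train + n_val, n))
    return train, val, test


def make_dataset(n: int, phantom: PhantomSpec, degr: DegradationSpec) -> SRDataset:
    """Generate n HR phantoms (seeds phantom.seed .. phantom.seed+n-1) with
    matched LR images (noise seeds degr.seed .. degr.seed+n-1)."""
    if n < 1:
        raise ContractError("n must be >= 1")
    hr_images, lr_images = [], []
    for i in range(n):
        pspec = PhantomSpec(
            modality=phantom.modality,
            size=phantom.size,
            n_ellipses=phantom.n_ellipses,
            speckle_strength=phantom.speckle_strength,
            seed=phantom.seed + i,
        )
        dspec = DegradationSpec(
            scale=degr.scale,
            blur_sigma=degr.blur_sigma,
            noise_sigma=degr.noise_sigma,
            seed=degr.seed + i,
        )
        hr = make_phantom(pspec)
        hr_images.append(hr)
        lr_images.append(degrade(hr, dspec))
    train, val, test = split_indices(n)
    return SRDataset(hr_images, lr_images, degr.scale, train, val, test)


# -- image I/O and manifests ---------------------------------------------


def read_image(path) -> np.ndarray:
    """Read PNG/TIFF/NPY as float32 in [0, 1] (integer images rescaled by
    their bit depth)."""
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
    elif path.suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.ndim == 3:  # collapse accidental RGB to single channel
        arr = arr.mean(axis=2)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def write_image(path, img: np.ndarray) -> None:
    """Write float [0, 1] image as 8-bit PNG, 16-bit TIFF or raw NPY by
    extension."""
    path = Path(path)
    img = np.clip(np.asarray(img, dtype=np.float32), 0.0, 1.0)
    if path.suffix == ".npy":
        np.save(path, img)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.round(img * 65535).astype(np.uint16))
    else:
        PILImage.fromarray(np.round(img * 255).astype(np.uint8)).save(path)


def write_dataset(dataset: SRDataset, outdir, fmt: str = "png") -> Path:
    """Write LR/HR pairs plus a plain-text manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = [f"# scale={dataset.scale}"]
    split_of = {}
    for name, idx in (("train", dataset.train_idx), ("val", dataset.val_idx), ("test", dataset.test_idx)):
        for i in idx:
            split_of[i] = name
    for i in range(len(dataset)):
        lr_path = outdir / f"pair{i:04d}_lr.{fmt}"
        hr_path = outdir / f"pair{i:04d}_hr.{fmt}"
        write_image(lr_path, dataset.lr[i])
        write_image(hr_path, dataset.hr[i])
        lines.append(f"{split_of[i]}\t{lr_path.name}\t{hr_path.name}")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_dataset(manifest_path) -> SRDataset:
    """Load a dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    scale = None
    hr_images, lr_images = [], []
    splits: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for line in manifest_path.read_text().splitlines():
        if line.startswith("#"):
            scale = int(line.split("scale=")[1])
            continue
        split, lr_name, hr_name = line.split("\t")
        splits[split].append(len(hr_images))
        lr_images.append(read_image(root / lr_name))
        hr_images.append(read_image(root / hr_name))
    if scale is None:
        raise ContractError("manifest missing scale header")
    return SRDataset(hr_images, lr_images, scale, splits["train"], splits["val"], splits["test"])
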