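"""Reference image-quality metrics: MSE, PSNR and SSIM.

PSNR is ``10*log10(MAX^2 / MSE)`` in decibels, with a ``+inf`` sentinel
for identical images.  SSIM is the windowed luminance/contrast/structure
index

    SSIM(x, y) = (2*mu_x*mu_y + c1)(2*sigma_xy + c2)
                 / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

averaged over all fully-valid window positions (no padding; borders are
excluded).  Local statistics use population (weighted) moments under the
window.  Defaults follow the standard convention: k1 = 0.01, k2 = 0.03,
11x11 Gaussian window with sigma 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .errors import ContractError


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ContractError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error; symmetric, >= 0, and 0 iff x == y."""
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB.

    ``max_i`` is the maximum possible pixel value (255 for 8-bit images,
    1.0 for normalised floats).  Identical images return ``inf``.
    """
    if max_i <= 0:
        raise ContractError("max_i must be positive")
    err = mse(x, y)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_i * max_i / err))


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Normalised 2-D Gaussian window."""
    half = (size - 1) / 2.0
    coords = np.arange(size) - half
    g = np.exp(-(coords**2) / (2.0 * sigma**2))
    win = np.outer(g, g)
    return win / win.sum()


def uniform_window(size: int) -> np.ndarray:
    return np.full((size, size), 1.0 / (size * size))


@dataclass
class SsimParams:
    """SSIM stabilizers and window.

    c1 = (k1*L)^2 and c2 = (k2*L)^2 guard the luminance and
    contrast/structure terms against division by weak denominators;
    L is the dynamic range of the pixel values.
    """

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0
    window: np.ndarray = field(default_factory=gaussian_window)

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.dynamic_range <= 0:
            raise ContractError("k1, k2 and dynamic_range must be positive")
        self.window = np.asarray(self.window, dtype=np.float64)
        if not np.isclose(self.window.sum(), 1.0):
            raise ContractError("window weights must sum to 1")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def ssim_map(x: np.ndarray, y: np.ndarray, params: SsimParams | None = None) -> np.ndarray:
    """Per-position SSIM over all fully-valid window placements."""
    params = params or SsimParams()
    x, y = _check_pair(x, y)
    win = params.window
    wh, ww = win.shape
    if x.shape[0] < wh or x.shape[1] < ww:
        raise ContractError(
            f"image {x.shape} smaller than window {win.shape}"
        )

    def local_mean(img: np.ndarray) -> np.ndarray:
        full = correlate(img, win, mode="constant")
        ty, tx = wh // 2, ww // 2
        by, bx = wh - 1 - ty, ww - 1 - tx
        return full[ty : img.shape[0] - by, tx : img.shape[1] - bx]

    mu_x = local_mean(x)
    mu_y = local_mean(y)
    var_x = local_mean(x * x) - mu_x**2
    var_y = local_mean(y * y) - mu_y**2
    cov = local_mean(x * y) - mu_x * mu_y
    c1, c2 = params.c1, params.c2
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return num / den


def ssim(x: np.ndarray, y: np.ndarray, params: SsimParams | None = None) -> float:
    """Mean SSIM; in [-1, 1], equal to 1 iff x == y."""
    return float(ssim_map(x, y, params).mean())
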