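"""Shade correction, CLAHE contrast enhancement and Gaussian denoising.

Shade correction estimates the slowly varying background as a large
median filter of the green plane, subtracts it, and re-centres on the
mean green level inside the FOV:

    I_bg = median(I_g),  I_eq = I_g − I_bg,  I_sc = I_eq + mean(I_g)

so the corrected image lives in the same gray range as the input while
illumination gradients slower than the median window are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure
from skimage.filters import rank

from fundusma.io_fov import FundusImage


@dataclass
class PreprocessedPlanes:
    """Derived planes of one image; values outside the FOV are zero."""

    i_sc: np.ndarray          # shade-corrected green plane
    i_clahe: np.ndarray       # CLAHE-enhanced i_sc
    i_gauss: np.ndarray       # 7×7-Gaussian-smoothed i_clahe
    mean_green: float         # mean of I_g over FOV pixels
    fov: np.ndarray
    green: np.ndarray


def median_background(green: np.ndarray, median_size: int = 50) -> np.ndarray:
    """Large-window median of the green plane (the background estimate).

    The window is adjusted up to the next odd size so it is centered.
    Computed with a sliding-histogram rank filter on the 8-bit grid
    (the green plane originates from 8-bit data), with explicit reflect
    padding so border semantics are well defined.
    """
    size = int(median_size)
    if size < 3:
        raise ValueError("median_size must be >= 3")
    if size % 2 == 0:
        size += 1
    if size > min(green.shape):
        raise ValueError("median window larger than the image")
    half = size // 2
    g8 = np.clip(np.rint(np.asarray(green, dtype=float) * 255.0), 0, 255).astype(np.uint8)
    padded = np.pad(g8, half, mode="reflect")
    med = rank.median(padded, footprint=np.ones((size, size), dtype=bool))
    return med[half:-half, half:-half].astype(np.float64) / 255.0


def shade_correct(img: FundusImage, median_size: int = 50) -> PreprocessedPlanes:
    """Apply the median-background shade correction inside the FOV."""
    fov = img.fov
    mean_green = float(img.green[fov].mean())
    i_bg = median_background(img.green, median_size)
    i_eq = img.green - i_bg
    i_sc = np.clip(i_eq + mean_green, 0.0, 1.0)
    i_sc[~fov] = 0.0
    return PreprocessedPlanes(i_sc=i_sc, i_clahe=np.zeros_like(i_sc),
                              i_gauss=np.zeros_like(i_sc),
                              mean_green=mean_green, fov=fov, green=img.green)


def enhance_contrast(i_sc: np.ndarray, fov: np.ndarray,
                     clip_limit: float = 0.05,
                     tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on [0, 1].

    ``clip_limit`` is the fraction-of-tile-pixels clip; ``tile_grid`` the
    number of tiles per axis. Output is rescaled to [0, 1] and zeroed
    outside the FOV.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    if min(tile_grid) < 2:
        raise ValueError("tile grid must be at least 2×2")
    arr = np.clip(np.asarray(i_sc, dtype=float), 0.0, 1.0)
    if np.ptp(arr[fov]) == 0:
        out = arr.copy()            # constant input: CLAHE is a no-op
    else:
        kernel = (max(1, arr.shape[0] // tile_grid[0]),
                  max(1, arr.shape[1] // tile_grid[1]))
        out = exposure.equalize_adapthist(arr, kernel_size=kernel, clip_limit=clip_limit)
        lo, hi = out[fov].min(), out[fov].max()
        if hi > lo:
            out = (out - lo) / (hi - lo)
    out = out.copy()
    out[~fov] = 0.0
    return out


def gaussian_kernel_2d(size: int = 7, sigma: float = 1.0) -> np.ndarray:
    """Truncated, renormalized 2-D Gaussian kernel (sums to 1)."""
    half = size // 2
    x = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-x**2 / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def denoise(i_clahe: np.ndarray, size: int = 7, sigma: float = 1.0) -> np.ndarray:
    """Smooth with the unit-sum truncated Gaussian kernel (reflect borders)."""
    k = gaussian_kernel_2d(size, sigma)
    return ndimage.convolve(np.asarray(i_clahe, dtype=float), k, mode="reflect")


def preprocess_image(img: FundusImage, median_size: int = 50,
                     clahe_clip_limit: float = 0.05,
                     clahe_tile_grid: tuple[int, int] = (8, 8),
                     gauss_size: int = 7, gauss_sigma: float = 1.0) -> PreprocessedPlanes:
    """Full preprocessing chain: shade correction → CLAHE → Gaussian."""
    planes = shade_correct(img, median_size)
    planes.i_clahe = enhance_contrast(planes.i_sc, planes.fov,
                                      clahe_clip_limit, clahe_tile_grid)
    planes.i_gauss = denoise(planes.i_clahe, gauss_size, gauss_sigma)
    planes.i_gauss[~planes.fov] = 0.0
    return planes
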