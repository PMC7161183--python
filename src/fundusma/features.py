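"""The 44-dimensional candidate-patch descriptor.

Ordered feature blocks (f1..f44):

  f1–f6    color: pooled mean/std of the RGB, HSV and CIELab patch
  f7–f10   grayscale: mean/std on the green plane and on I_CLAHE
  f11–f22  directional local contrast (DLC) at 12 angles, radius 12
  f23–f28  shape: Area, Perimeter, Circularity, Eccentricity,
           Aspect ratio, Solidity of the candidate region
  f29–f32  texture: Entropy, Energy, Homogeneity, Skewness on I_CLAHE
  f33–f40  mean/std of Gaussian-filtered I_CLAHE at σ ∈ {1, 2, 4, 8}
  f41–f44  mean dx/dy over the patch and over the region boundary

The DLC of the patch center p along a ray at angle θ is the relative
contrast against the mean intensity sampled at k = 1..r steps along
the ray:

    DLC_p(θ) = (I_p − Ī_p(θ)) / Ī_p(θ)

A microaneurysm — an isolated dark dot — has strongly negative DLC in
every direction, which is what separates it from vessels (negative only
across the tube), hemorrhages (neighborhood as dark as the center) and
background (≈ 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage.feature import graycomatrix

from fundusma.candidates import CandidatePatch, CandidateRegion, cut_window
from fundusma.preprocess import PreprocessedPlanes

FEATURE_NAMES: tuple[str, ...] = (
    "rgb_mean", "rgb_std", "hsv_mean", "hsv_std", "lab_mean", "lab_std",
    "green_mean", "green_std", "clahe_mean", "clahe_std",
    *[f"dlc_{30 * i:03d}" for i in range(12)],
    "area", "perimeter", "circularity", "eccentricity", "aspect_ratio", "solidity",
    "entropy", "energy", "homogeneity", "skewness",
    *[f"gauss_s{s}_{stat}" for s in (1, 2, 4, 8) for stat in ("mean", "std")],
    "grad_dx_mean", "grad_dy_mean", "grad_dx_boundary", "grad_dy_boundary",
)
assert len(FEATURE_NAMES) == 44

_DLC_EPS = 1.0 / 255.0


@dataclass
class DlcVector:
    dlc: np.ndarray          # 12 values, angles 0°,30°,...,330°
    radius: int
    center_value: float


@dataclass
class PatchFeatureVector:
    values: np.ndarray       # 44 floats, order of FEATURE_NAMES
    names: tuple[str, ...] = FEATURE_NAMES


def dlc(window: np.ndarray, radius: int = 12, n_angles: int = 12,
        interpolation: str = "nearest") -> DlcVector:
    """Directional local contrast of the window center.

    Rays at ``n_angles`` evenly spaced angles; along each ray, intensities
    at k = 1..radius steps are averaged into Ī, and the component is
    (I_p − Ī)/Ī.  Ī is floored at 1/255 since an equalized plane can
    contain exact zeros.
    """
    w = np.asarray(window, dtype=float)
    cy, cx = w.shape[0] // 2, w.shape[1] // 2
    if radius > min(cy, cx):
        raise ValueError("radius exceeds the window half-size")
    i_p = float(w[cy, cx])
    out = np.empty(n_angles)
    ks = np.arange(1, radius + 1, dtype=float)
    for a in range(n_angles):
        theta = 2.0 * np.pi * a / n_angles
        xs = cx + ks * np.cos(theta)
        ys = cy + ks * np.sin(theta)
        if interpolation == "bilinear":
            samples = ndimage.map_coordinates(w, [ys, xs], order=1, mode="nearest")
        else:
            rr = np.rint(ys).astype(int)
            cc = np.rint(xs).astype(int)
            samples = w[rr, cc]
        mean_i = max(float(samples.mean()), _DLC_EPS)
        out[a] = (i_p - mean_i) / mean_i
    return DlcVector(dlc=out, radius=radius, center_value=i_p)


def color_stats(window_rgb: np.ndarray) -> np.ndarray:
    """Pooled mean/std of the patch in RGB, HSV and CIELab (f1..f6).

    Per color space the three channels' pixel values are pooled into one
    sample; stds are population stds.
    """
    rgb = np.asarray(window_rgb, dtype=float)
    hsv = skcolor.rgb2hsv(rgb)
    lab = skcolor.rgb2lab(rgb)
    out = []
    for space in (rgb, hsv, lab):
        flat = space.reshape(-1)
        out.extend([float(flat.mean()), float(flat.std())])
    return np.asarray(out)


def grayscale_stats(window_g: np.ndarray, window_clahe: np.ndarray) -> np.ndarray:
    """Mean/std of the patch on I_g and on I_CLAHE (f7..f10)."""
    out = []
    for w in (window_g, window_clahe):
        w = np.asarray(w, dtype=float)
        out.extend([float(w.mean()), float(w.std())])
    return np.asarray(out)


def shape_features(region: CandidateRegion) -> np.ndarray:
    """Area, Perimeter, Circularity, Eccentricity, Aspect ratio, Solidity.

    Circularity = Perimeter² / (4π·Area); Eccentricity = c/a of the
    moment-matched ellipse (= sqrt(1 − (b/a)²)); Solidity = Area / convex
    hull area.  The minor axis is floored at 0.5 px so single-pixel
    regions have a finite aspect ratio.
    """
    area = float(region.area)
    perim = float(region.perimeter)
    circularity = perim ** 2 / (4.0 * np.pi * area)
    a = region.major_axis / 2.0
    b = region.minor_axis / 2.0
    ecc = float(np.sqrt(max(0.0, 1.0 - (b / a) ** 2))) if a > 0 else 0.0
    aspect = region.major_axis / max(region.minor_axis, 0.5) if region.major_axis > 0 else 1.0
    solidity = area / _convex_area(region.pixels)
    return np.asarray([area, perim, circularity, ecc, aspect, solidity])


def _convex_area(pixels: np.ndarray) -> float:
    """Pixel count of the filled convex hull of the region (≥ area)."""
    from skimage.morphology import convex_hull_image

    rows, cols = pixels[:, 0], pixels[:, 1]
    r0, c0 = rows.min(), cols.min()
    sub = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    sub[rows - r0, cols - c0] = True
    if sub.sum() <= 2:
        return float(sub.sum())
    # pixel-center hull: a rasterized convex region is its own hull
    return float(convex_hull_image(sub, offset_coordinates=False).sum())


def quantize_levels(window: np.ndarray, levels: int = 8) -> np.ndarray:
    """Quantize a [0,1] window to integer gray levels 0..levels−1."""
    w = np.clip(np.asarray(window, dtype=float), 0.0, 1.0)
    return np.minimum((w * levels).astype(int), levels - 1)


def glcm_matrix(quantized: np.ndarray, levels: int = 8) -> np.ndarray:
    """Symmetric normalized GLCM at distance 1, averaged over 4 orientations."""
    g = graycomatrix(quantized.astype(np.uint8), distances=[1],
                     angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                     levels=levels, symmetric=True, normed=True)
    return g[:, :, 0, :].mean(axis=2)


def texture_features(window_clahe: np.ndarray, levels: int = 8) -> np.ndarray:
    """Entropy, Energy, Homogeneity, Skewness of the patch (f29..f32).

    Entropy is computed over the histogram of the 8-level quantized
    window; Energy and Homogeneity from the averaged normalized GLCM;
    Skewness from the raw intensities (0 for a zero-variance window).
    """
    q = quantize_levels(window_clahe, levels)
    counts = np.bincount(q.ravel(), minlength=levels).astype(float)
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    glcm = glcm_matrix(q, levels)
    energy = float((glcm ** 2).sum())
    i, j = np.indices(glcm.shape)
    homogeneity = float((glcm / (1.0 + np.abs(i - j))).sum())
    w = np.asarray(window_clahe, dtype=float).ravel()
    sd = w.std()
    skewness = float(((w - w.mean()) ** 3).mean() / sd ** 3) if sd > 0 else 0.0
    return np.asarray([entropy, energy, homogeneity, skewness])


def gaussian_bank_features(i_clahe: np.ndarray, center: tuple[int, int],
                           sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
                           patch_size: int = 25,
                           filtered: list[np.ndarray] | None = None) -> np.ndarray:
    """Mean/std of Gaussian-filtered I_CLAHE inside the window (f33..f40).

    Filtering acts on the full plane (not the cut patch) to avoid
    patch-border bias; ``filtered`` may carry precomputed planes when
    many patches share one image.
    """
    if filtered is None:
        filtered = gaussian_bank_planes(i_clahe, sigmas)
    out = []
    for plane in filtered:
        win = cut_window(plane, center, patch_size)
        out.extend([float(win.mean()), float(win.std())])
    return np.asarray(out)


def gaussian_bank_planes(i_clahe: np.ndarray,
                         sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)) -> list[np.ndarray]:
    return [ndimage.gaussian_filter(np.asarray(i_clahe, dtype=float), s, mode="reflect")
            for s in sigmas]


def gradient_features(window_clahe: np.ndarray, region: CandidateRegion,
                      plane: np.ndarray | None = None) -> np.ndarray:
    """Mean signed dx/dy over the patch and over the region boundary.

    Gradients are central differences.  Boundary gradients are sampled on
    the full plane at the region's boundary pixels when ``plane`` is
    given; otherwise boundary pixels are mapped into window coordinates.
    """
    w = np.asarray(window_clahe, dtype=float)
    dy_w, dx_w = np.gradient(w)
    f41, f42 = float(dx_w.mean()), float(dy_w.mean())
    if plane is not None:
        dy_p, dx_p = np.gradient(np.asarray(plane, dtype=float))
        rr, cc = region.boundary_pixels[:, 0], region.boundary_pixels[:, 1]
        f43, f44 = float(dx_p[rr, cc].mean()), float(dy_p[rr, cc].mean())
    else:
        half = w.shape[0] // 2
        cy, cx = region.centroid
        rr = np.clip(np.rint(region.boundary_pixels[:, 0] - cy + half).astype(int), 0, w.shape[0] - 1)
        cc = np.clip(np.rint(region.boundary_pixels[:, 1] - cx + half).astype(int), 0, w.shape[1] - 1)
        f43, f44 = float(dx_w[rr, cc].mean()), float(dy_w[rr, cc].mean())
    return np.asarray([f41, f42, f43, f44])


def extract_all(patch: CandidatePatch, planes: PreprocessedPlanes,
                dlc_radius: int = 12, dlc_n_angles: int = 12,
                gaussian_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
                gaussian_planes: list[np.ndarray] | None = None) -> PatchFeatureVector:
    """Concatenate all feature blocks in the fixed order; length 44."""
    parts = [
        color_stats(patch.window_rgb),
        grayscale_stats(patch.window_green, patch.window),
        dlc(patch.window, dlc_radius, dlc_n_angles).dlc,
        shape_features(patch.region),
        texture_features(patch.window),
        gaussian_bank_features(planes.i_clahe, patch.center, gaussian_sigmas,
                               patch.window.shape[0], filtered=gaussian_planes),
        gradient_features(patch.window, patch.region, plane=planes.i_clahe),
    ]
    values = np.concatenate(parts)
    if values.shape[0] != 44:
        raise AssertionError(f"feature vector has length {values.shape[0]}, expected 44")
    if not np.all(np.isfinite(values)):
        bad = [FEATURE_NAMES[i] for i in np.nonzero(~np.isfinite(values))[0]]
        raise ValueError(f"non-finite feature value(s): {bad}")
    return PatchFeatureVector(values=values)


def extract_feature_matrix(patches: list[CandidatePatch], planes: PreprocessedPlanes,
                           dlc_radius: int = 12, dlc_n_angles: int = 12,
                           gaussian_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)) -> np.ndarray:
    """Feature matrix (n_patches × 44) with shared Gaussian-bank planes."""
    if not patches:
        return np.empty((0, 44))
    gplanes = gaussian_bank_planes(planes.i_clahe, gaussian_sigmas)
    return np.vstack([
        extract_all(p, planes, dlc_radius, dlc_n_angles, gaussian_sigmas,
                    gaussian_planes=gplanes).values
        for p in patches
    ])
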