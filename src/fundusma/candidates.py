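"""MA candidate extraction: vessel removal, contrast stretch, shape filters.

After the vessel main structure is zeroed out of the denoised plane, the
remaining dark structures — lesions, noise and small vessel fragments —
are isolated by Otsu binarization of the contrast-stretched plane.
Connected components are then filtered by elongation (slender vessel
fragments have a large major/minor axis ratio R) and by area (true MAs
are small; anything above the area cap is a hemorrhage or artifact):

    R threshold = ratio_multiplier × mean(R over preliminary regions)

with ratio_multiplier 1.2 and an area cap of 500 px.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from fundusma.preprocess import PreprocessedPlanes


@dataclass
class CandidateRegion:
    """One connected component surviving the candidate filters."""

    pixels: np.ndarray                # (n, 2) int array of (row, col)
    centroid: tuple[float, float]
    area: int
    perimeter: float                  # boundary length, diagonal steps weighted √2
    major_axis: float
    minor_axis: float
    axis_ratio: float                 # R = major / max(minor, 0.5)
    boundary_pixels: np.ndarray       # (m, 2) int array
    label: int = 0


@dataclass
class CandidatePatch:
    """25×25 windows around one candidate region's centroid."""

    region: CandidateRegion
    window: np.ndarray                # from I_CLAHE
    window_rgb: np.ndarray            # from the original RGB, floats in [0,1]
    window_green: np.ndarray          # from I_g
    center: tuple[int, int]           # rounded centroid (row, col)

    @property
    def center_value(self) -> float:
        h = self.window.shape[0] // 2
        return float(self.window[h, h])


def remove_vessels(i_gauss: np.ndarray, vessel_mask: np.ndarray) -> np.ndarray:
    """Zero out the segmented vessel pixels (I_gsBV0)."""
    if i_gauss.shape != vessel_mask.shape:
        raise ValueError("shape mismatch between plane and vessel mask")
    out = np.asarray(i_gauss, dtype=float).copy()
    out[np.asarray(vessel_mask, dtype=bool)] = 0.0
    return out


def contrast_stretch(i_gsbv0: np.ndarray, mean_green: float, fov: np.ndarray,
                     mode: str = "minmax",
                     percentiles: tuple[float, float] = (1.0, 99.0)) -> np.ndarray:
    """Subtract the FOV-mean green level and stretch FOV values to [0, 1]."""
    fov = np.asarray(fov, dtype=bool)
    shifted = np.asarray(i_gsbv0, dtype=float) - float(mean_green)
    vals = shifted[fov]
    if vals.size == 0:
        raise ValueError("empty FOV")
    if mode == "percentile":
        lo, hi = np.percentile(vals, percentiles)
    else:
        lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros_like(shifted)
    if hi <= lo:
        warnings.warn("contrast_stretch: constant input inside FOV", stacklevel=2)
        return out
    out[fov] = np.clip((shifted[fov] - lo) / (hi - lo), 0.0, 1.0)
    return out


def _region_from_slice(mask: np.ndarray, label: int) -> CandidateRegion:
    rows, cols = np.nonzero(mask)
    pixels = np.column_stack([rows, cols]).astype(int)
    area = len(pixels)
    centroid = (float(rows.mean()), float(cols.mean()))
    # boundary: region pixels with at least one 4-neighbor outside the region
    interior = ndimage.binary_erosion(mask, structure=np.array([[0, 1, 0],
                                                                [1, 1, 1],
                                                                [0, 1, 0]]),
                                      border_value=0)
    bmask = mask & ~interior
    brows, bcols = np.nonzero(bmask)
    boundary = np.column_stack([brows, bcols]).astype(int)
    props = measure.regionprops(mask.astype(np.uint8))[0]
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    ratio = major / max(minor, 0.5) if major > 0 else 1.0
    if minor == 0 and area > 1:
        ratio = np.inf            # degenerate 1-px-wide line
    perim = float(props.perimeter) if area > 1 else 1.0
    return CandidateRegion(pixels=pixels, centroid=centroid, area=area,
                           perimeter=perim, major_axis=major,
                           minor_axis=minor, axis_ratio=ratio,
                           boundary_pixels=boundary, label=label)


def regions_from_mask(binary: np.ndarray) -> list[CandidateRegion]:
    """8-connected components of a binary mask as ``CandidateRegion`` objects."""
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    regions = []
    for obj_slice, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        sub = labels[obj_slice] == lab
        reg = _region_from_slice(sub, lab)
        off = np.array([obj_slice[0].start, obj_slice[1].start])
        reg.pixels = reg.pixels + off
        reg.boundary_pixels = reg.boundary_pixels + off
        reg.centroid = (reg.centroid[0] + off[0], reg.centroid[1] + off[1])
        regions.append(reg)
    return regions


def extract_candidates(i_cs: np.ndarray, fov: np.ndarray,
                       ratio_multiplier: float = 1.2,
                       max_area: int = 500) -> list[CandidateRegion]:
    """Binarize the stretched plane and filter components by R and area.

    Candidate foreground is the dark (below-Otsu) class restricted to
    strictly positive stretched values, so zeroed vessel pixels and the
    outside of the FOV can never seed a region.  The slender-structure
    threshold is ``ratio_multiplier × mean(R)`` over the preliminary
    regions (single pass); regions above it, and regions larger than
    ``max_area``, are discarded.
    """
    from fundusma.vessels import otsu_threshold

    fov = np.asarray(fov, dtype=bool)
    thr, degenerate = otsu_threshold(i_cs, fov)
    if degenerate:
        return []
    binary = (i_cs < thr) & (i_cs > 0) & fov
    prelim = regions_from_mask(binary)
    return filter_by_shape(prelim, ratio_multiplier, max_area)


def filter_by_shape(prelim: list[CandidateRegion], ratio_multiplier: float = 1.2,
                    max_area: int = 500) -> list[CandidateRegion]:
    """Single-pass slender-structure (R) and area filters on preliminary regions."""
    if not prelim:
        return []
    ratios = np.array([r.axis_ratio for r in prelim])
    finite = ratios[np.isfinite(ratios)]
    mean_ratio = float(finite.mean()) if finite.size else 1.0
    r_threshold = ratio_multiplier * mean_ratio
    return [r for r in prelim
            if np.isfinite(r.axis_ratio) and r.axis_ratio <= r_threshold
            and r.area <= max_area]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def cut_window(plane: np.ndarray, center: tuple[int, int], size: int) -> np.ndarray:
    """Size×size window around ``center`` with reflect padding at borders."""
    half = size // 2
    pad_width = ((half, half), (half, half)) + ((0, 0),) * (plane.ndim - 2)
    padded = np.pad(plane, pad_width, mode="reflect")
    r, c = center
    return padded[r:r + size, c:c + size].copy()


def cut_patches(planes: PreprocessedPlanes, rgb: np.ndarray,
                regions: list[CandidateRegion], patch_size: int = 25) -> list[CandidatePatch]:
    """Cut one patch per region, centered on the rounded centroid."""
    if patch_size % 2 == 0:
        raise ValueError("patch_size must be odd")
    rgbf = np.asarray(rgb, dtype=float)
    if rgbf.max() > 1.0:
        rgbf = rgbf / 255.0
    patches = []
    for reg in regions:
        center = (_round_half_up(reg.centroid[0]), _round_half_up(reg.centroid[1]))
        patches.append(CandidatePatch(
            region=reg,
            window=cut_window(planes.i_clahe, center, patch_size),
            window_rgb=cut_window(rgbf, center, patch_size),
            window_green=cut_window(planes.green, center, patch_size),
            center=center,
        ))
    return patches
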