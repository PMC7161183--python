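"""Multi-scale Hessian-eigenvalue vessel enhancement and segmentation.

At each Gaussian scale σ the image's second derivatives L_xx, L_xy, L_yy
form the Hessian

    H = [[L_xx, L_xy], [L_xy, L_yy]]

whose eigenvalues are ordered so |λ2| ≥ |λ1|.  On a dark tube over a
brighter background λ2 is large and positive across the tube.  The
enhancement response normalizes λ2 by λρ, the largest positive λ2 in
the field of view at that scale:

    E = 0                                   if λ2 ≤ 0 or λρ ≤ 0
    E = 1                                   if λ2 ≥ λρ/2 > 0
    E = λ2²(λρ − λ2)(3/(λ2 + λρ))³          otherwise

which is bounded on [0, 1] and peaks at λ2 = λρ/2.  The final vessel
mask is the Otsu binarization of the scale-wise maximum response with
small components removed, leaving the vessel *main structure* so that
dot-like lesions caught by the enhancement survive as candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class HessianField:
    """Second derivatives and ordered eigenvalue rasters at one scale."""

    lxx: np.ndarray
    lxy: np.ndarray
    lyy: np.ndarray
    lambda1: np.ndarray      # |lambda1| <= |lambda2| everywhere
    lambda2: np.ndarray
    sigma: float


@dataclass
class VesselSegmentation:
    enhanced: np.ndarray     # max-over-scales response, in [0, 1]
    mask: np.ndarray         # boolean vessel main-structure mask
    min_region_area: float
    threshold: float | None  # Otsu threshold used (None when degenerate)


def hessian_eigenvalues(lxx: np.ndarray, lxy: np.ndarray,
                        lyy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form 2×2 symmetric eigenvalues, ordered |λ2| ≥ |λ1|."""
    tmp = np.sqrt((lxx - lyy) ** 2 + 4.0 * lxy ** 2)
    mu1 = 0.5 * (lxx + lyy + tmp)
    mu2 = 0.5 * (lxx + lyy - tmp)
    swap = np.abs(mu1) <= np.abs(mu2)
    lambda1 = np.where(swap, mu1, mu2)
    lambda2 = np.where(swap, mu2, mu1)
    return lambda1, lambda2


def hessian_at_scale(i_sc: np.ndarray, sigma: float) -> HessianField:
    """σ²-normalized Gaussian-derivative Hessian of the image at scale σ.

    The σ² factor (γ = 2 scale normalization) keeps responses comparable
    across scales so the multi-scale maximum is meaningful.
    """
    if sigma < 1:
        raise ValueError("sigma must be >= 1")
    img = np.asarray(i_sc, dtype=float)
    s2 = sigma * sigma
    # axis 0 = rows = y, axis 1 = cols = x
    lxx = s2 * ndimage.gaussian_filter(img, sigma, order=(0, 2), mode="reflect")
    lyy = s2 * ndimage.gaussian_filter(img, sigma, order=(2, 0), mode="reflect")
    lxy = s2 * ndimage.gaussian_filter(img, sigma, order=(1, 1), mode="reflect")
    lambda1, lambda2 = hessian_eigenvalues(lxx, lxy, lyy)
    return HessianField(lxx=lxx, lxy=lxy, lyy=lyy,
                        lambda1=lambda1, lambda2=lambda2, sigma=sigma)


def enhancement_response(lambda2: np.ndarray, fov: np.ndarray | None = None,
                         lambda_rho: float | None = None) -> np.ndarray:
    """Normalized tubular-enhancement response on [0, 1].

    λρ defaults to the largest positive λ2 inside ``fov`` (whole image if
    no mask given); it can be passed explicitly when a joint-over-scales
    normalization is wanted.
    """
    l2 = np.asarray(lambda2, dtype=float)
    if lambda_rho is None:
        sel = l2[fov] if fov is not None else l2.ravel()
        pos = sel[sel > 0]
        lambda_rho = float(pos.max()) if pos.size else 0.0
    resp = np.zeros_like(l2)
    if lambda_rho <= 0:
        return resp
    mid = (l2 > 0) & (l2 < lambda_rho / 2.0)
    resp[l2 >= lambda_rho / 2.0] = 1.0
    x = l2[mid]
    resp[mid] = x ** 2 * (lambda_rho - x) * (3.0 / (x + lambda_rho)) ** 3
    return resp


def otsu_threshold(values: np.ndarray, mask: np.ndarray | None = None,
                   nbins: int = 256) -> tuple[float, bool]:
    """Otsu threshold over a 256-bin histogram of masked values.

    Returns ``(threshold, degenerate)``; ``degenerate`` is True for a
    constant input, in which case the caller decides the outcome.
    """
    vals = np.asarray(values, dtype=float)
    if mask is not None:
        vals = vals[np.asarray(mask, dtype=bool)]
    vals = vals.ravel()
    if vals.size == 0:
        raise ValueError("otsu_threshold: empty sample")
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin == vmax:
        return vmin, True
    hist, edges = np.histogram(vals, bins=nbins, range=(vmin, vmax))
    p = hist.astype(float) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)
    m = np.cumsum(p * centers)
    m_total = m[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (m_total * w0 - m) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between[:-1]))       # last cut leaves class 1 empty
    return float(edges[k + 1]), False


def segment_vessels(i_sc: np.ndarray, fov: np.ndarray,
                    sigmas: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0),
                    min_region_area: float = 400.0,
                    reference_fov_area: float | None = None,
                    lambda_rho_scope: str = "per_scale") -> VesselSegmentation:
    """Segment the blood-vessel main structure of a shade-corrected plane.

    ``min_region_area`` is an absolute pixel cutoff chosen to exceed the
    largest annotated MA, so dot lesions caught by the enhancement are
    dropped from the mask.  Pass ``reference_fov_area`` to rescale it by
    the actual FOV area when working across camera resolutions.
    """
    fov = np.asarray(fov, dtype=bool)
    if not fov.any():
        raise ValueError("empty FOV")
    fields = [hessian_at_scale(i_sc, s) for s in sigmas]
    if lambda_rho_scope == "joint":
        all_pos = [f.lambda2[fov][f.lambda2[fov] > 0] for f in fields]
        flat = np.concatenate([a for a in all_pos if a.size]) if any(a.size for a in all_pos) else np.array([])
        rho = float(flat.max()) if flat.size else 0.0
        responses = [enhancement_response(f.lambda2, fov, lambda_rho=rho) for f in fields]
    else:
        responses = [enhancement_response(f.lambda2, fov) for f in fields]
    enhanced = np.maximum.reduce(responses)
    enhanced[~fov] = 0.0

    area = float(min_region_area)
    if reference_fov_area:
        area *= fov.sum() / reference_fov_area
    thr, degenerate = otsu_threshold(enhanced, fov)
    if degenerate:
        # no evidence of vessels: remove nothing
        mask = np.zeros_like(fov)
        return VesselSegmentation(enhanced=enhanced, mask=mask,
                                  min_region_area=area, threshold=None)
    mask = (enhanced > thr) & fov
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        keep = np.concatenate([[False], sizes >= area])
        mask = keep[labels]
    return VesselSegmentation(enhanced=enhanced, mask=mask,
                              min_region_area=area, threshold=thr)
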