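"""Seeded synthetic fundus scenes with exact ground truth.

The generator emulates the phenomenology the detection pipeline relies
on — a circular field of view on a dark surround, smooth illumination
shading, a dark branching-ish vessel network with Gaussian cross
profile, small dark circular microaneurysms (MAs), larger irregular
blurred hemorrhages, and additive pixel noise — not photorealism.  RGB
is synthesized red-dominant so the green channel is the informative
plane, as in real fundus photographs.  Identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from fundusma.io_fov import FundusImage, LesionAnnotation, fundus_from_array, write_annotations


# Contrast floor (fraction of local background) above which every planted
# MA is expected to surface as a candidate; scenes drawn at or above this
# floor are the "easy contrast" benchmark condition.
MA_CONTRAST_FLOOR = 0.3


def easy_benchmark_spec(**overrides) -> "SceneSpec":
    """Default scene with MA contrasts at or above the stated floor."""
    spec = SceneSpec(ma_contrast_range=(MA_CONTRAST_FLOOR, 0.45))
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


@dataclass
class SceneSpec:
    """Study conditions for one synthetic scene."""

    shape: tuple[int, int] = (960, 960)
    fov_radius: int = 440
    n_vessels: int = 8
    vessel_width_range: tuple[float, float] = (6.0, 14.0)
    n_ma: int = 15
    ma_diameter_range: tuple[float, float] = (3.0, 12.0)
    ma_contrast_range: tuple[float, float] = (0.2, 0.4)   # fraction of background
    n_hemorrhage: int = 2
    hemorrhage_area_range: tuple[float, float] = (700.0, 2000.0)
    shading_amplitude: float = 0.15
    noise_sigma: float = 0.01
    background_level: float = 0.55
    vessel_contrast: float = 0.45
    allow_vessel_adjacent_ma: bool = False
    seed: int = 0


@dataclass
class SceneTruth:
    ma_centroids: list[tuple[int, int]]
    ma_mask: np.ndarray
    vessel_mask: np.ndarray
    hemorrhage_mask: np.ndarray
    background_level: np.ndarray
    hemorrhage_centroids: list[tuple[int, int]] = field(default_factory=list)


def _fov_mask(shape: tuple[int, int], radius: int) -> np.ndarray:
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    cy, cx = shape[0] / 2.0, shape[1] / 2.0
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= radius ** 2


def _smooth_shading(shape: tuple[int, int], amplitude: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Low-frequency multiplicative shading field around 1.0."""
    rows, cols = shape
    yy, xx = np.mgrid[:rows, :cols]
    f = np.zeros(shape, dtype=float)
    for _ in range(3):
        cy = rng.uniform(0, rows)
        cx = rng.uniform(0, cols)
        s = rng.uniform(0.4, 0.9) * max(rows, cols)
        a = rng.uniform(-1.0, 1.0)
        f += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s ** 2))
    if np.ptp(f) > 0:
        f = (f - f.min()) / np.ptp(f) - 0.5
    return 1.0 + amplitude * 2.0 * f


def _vessel_depth(spec: SceneSpec, fov: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Attenuation depth field and mask for the vessel network.

    Each vessel is a curvature-bounded random walk crossing the FOV,
    rendered with a Gaussian cross profile of the sampled width.
    """
    rows, cols = spec.shape
    cy, cx = rows / 2.0, cols / 2.0
    depth = np.zeros(spec.shape, dtype=float)
    mask = np.zeros(spec.shape, dtype=bool)
    for _ in range(spec.n_vessels):
        width = rng.uniform(*spec.vessel_width_range)
        phi0 = rng.uniform(0, 2 * np.pi)
        r0 = spec.fov_radius - 4
        y, x = cy + r0 * np.sin(phi0), cx + r0 * np.cos(phi0)
        heading = phi0 + np.pi + rng.uniform(-0.4, 0.4)   # roughly inward
        path = np.zeros(spec.shape, dtype=bool)
        for _ in range(int(3.2 * spec.fov_radius)):
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < rows and 0 <= ix < cols:
                path[iy, ix] = True
            y += np.sin(heading)
            x += np.cos(heading)
            heading += rng.normal(0.0, 0.05)
            if (y - cy) ** 2 + (x - cx) ** 2 > (spec.fov_radius + 6) ** 2:
                break
        if not path.any():
            continue
        dist = ndimage.distance_transform_edt(~path)
        sigma_w = width / 2.355                      # FWHM = width
        depth = np.maximum(depth, np.exp(-dist ** 2 / (2 * sigma_w ** 2)))
        mask |= dist <= width / 2.0
    depth[~fov] = 0.0
    mask &= fov
    return depth, mask


def _place_points(n: int, fov: np.ndarray, forbidden: np.ndarray,
                  rng: np.random.Generator, margin: int, min_sep: float,
                  max_tries: int = 4000) -> list[tuple[int, int]]:
    rows, cols = fov.shape
    cy, cx = rows / 2.0, cols / 2.0
    pts: list[tuple[int, int]] = []
    tries = 0
    while len(pts) < n and tries < max_tries:
        tries += 1
        r = int(rng.integers(margin, rows - margin))
        c = int(rng.integers(margin, cols - margin))
        if not fov[r, c] or forbidden[r, c]:
            continue
        if any((r - pr) ** 2 + (c - pc) ** 2 < min_sep ** 2 for pr, pc in pts):
            continue
        pts.append((r, c))
    if len(pts) < n:
        raise ValueError(f"could not place {n} lesions after {max_tries} tries; "
                         "reduce lesion count or density")
    return pts


def _irregular_blob(area: float, rng: np.random.Generator) -> np.ndarray:
    """Filled irregular blob mask of roughly the requested area."""
    r0 = np.sqrt(area / np.pi)
    n_theta = 720
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    radius = np.full(n_theta, r0)
    for harm in range(2, 6):
        amp = rng.uniform(0.0, 0.25) * r0
        phase = rng.uniform(0, 2 * np.pi)
        radius += amp * np.cos(harm * theta + phase)
    radius = np.clip(radius, 1.0, None)
    size = int(2 * radius.max() + 5)
    yy, xx = np.mgrid[:size, :size]
    c = size / 2.0
    ang = np.arctan2(yy - c, xx - c) % (2 * np.pi)
    rr = np.hypot(yy - c, xx - c)
    idx = (ang / (2 * np.pi) * n_theta).astype(int) % n_theta
    return rr <= radius[idx]


def generate_scene(spec: SceneSpec) -> tuple[FundusImage, SceneTruth]:
    """Render one scene and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    fov = _fov_mask(spec.shape, spec.fov_radius)
    shading = _smooth_shading(spec.shape, spec.shading_amplitude, rng)
    background = spec.background_level * shading

    vessel_depth, vessel_mask = _vessel_depth(spec, fov, rng)

    # forbid MA placement on (dilated) vessels unless explicitly allowed
    if spec.allow_vessel_adjacent_ma:
        forbidden = np.zeros(spec.shape, dtype=bool)
    else:
        forbidden = ndimage.binary_dilation(vessel_mask, iterations=6)
    margin = max(20, int(np.ceil(max(spec.ma_diameter_range))))
    rim = ~_fov_mask(spec.shape, spec.fov_radius - margin)
    ma_centers = _place_points(spec.n_ma, fov & ~rim, forbidden, rng,
                               margin=margin, min_sep=30.0)

    ma_depth = np.zeros(spec.shape, dtype=float)
    ma_mask = np.zeros(spec.shape, dtype=bool)
    yy, xx = np.mgrid[:rows, :cols]
    for (r, c) in ma_centers:
        d = rng.uniform(*spec.ma_diameter_range)
        contrast = rng.uniform(*spec.ma_contrast_range)
        sigma_d = max(d / 3.0, 0.7)
        r2 = (yy - r) ** 2 + (xx - c) ** 2
        support = r2 <= (d / 2.0 + 1.0) ** 2            # sharp border
        ma_depth = np.maximum(ma_depth, contrast * np.exp(-r2 / (2 * sigma_d ** 2)) * support)
        ma_mask |= r2 <= (d / 2.0) ** 2

    hm_forbidden = (ndimage.binary_dilation(vessel_mask, iterations=4)
                    | ndimage.binary_dilation(ma_mask, iterations=25))
    hm_centers = _place_points(spec.n_hemorrhage, fov & ~rim, hm_forbidden, rng,
                               margin=60, min_sep=120.0) if spec.n_hemorrhage else []
    hm_depth = np.zeros(spec.shape, dtype=float)
    hm_mask = np.zeros(spec.shape, dtype=bool)
    for (r, c) in hm_centers:
        area = rng.uniform(*spec.hemorrhage_area_range)
        blob = _irregular_blob(area, rng)
        contrast = rng.uniform(*spec.ma_contrast_range)
        h = np.zeros(spec.shape, dtype=float)
        br, bc = blob.shape
        r0, c0 = r - br // 2, c - bc // 2
        rs, cs = slice(max(r0, 0), min(r0 + br, rows)), slice(max(c0, 0), min(c0 + bc, cols))
        h[rs, cs] = blob[(rs.start - r0):(rs.stop - r0), (cs.start - c0):(cs.stop - c0)]
        hm_mask |= h > 0.5
        h = ndimage.gaussian_filter(h, 3.0)             # blurred border
        hm_depth = np.maximum(hm_depth, contrast * h)

    depth = np.maximum(np.maximum(spec.vessel_contrast * vessel_depth, ma_depth), hm_depth)
    green = background * (1.0 - depth)
    green += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    green = np.clip(green, 0.0, 1.0)
    green[~fov] = 0.01

    red = np.clip(green * 1.35 + 0.25, 0.0, 1.0)
    blue = np.clip(green * 0.35, 0.0, 1.0)
    rgb = np.stack([red, green, blue], axis=2)
    rgb[~fov] = 0.0
    rgb8 = np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)

    img = fundus_from_array(rgb8, image_id=f"synth_{spec.seed:08d}")
    truth = SceneTruth(ma_centroids=ma_centers, ma_mask=ma_mask & fov,
                       vessel_mask=vessel_mask,
                       hemorrhage_mask=hm_mask & fov,
                       background_level=background,
                       hemorrhage_centroids=hm_centers)
    return img, truth


def make_benchmark(n_images: int, spec: SceneSpec, seed: int,
                   out_dir: str | Path) -> dict:
    """Write a benchmark dataset: PNGs, truth CSV, manifest, train/test split."""
    if n_images < 2:
        raise ValueError("need at least 2 images for a train/test split")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    image_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    annotations = []
    image_ids = []
    checksums = {}
    for s in image_seeds:
        sp = SceneSpec(**{**asdict(spec), "seed": int(s)})
        img, truth = generate_scene(sp)
        image_ids.append(img.image_id)
        png = out / f"{img.image_id}.png"
        Image.fromarray(img.rgb).save(png)
        checksums[img.image_id] = hashlib.sha256(png.read_bytes()).hexdigest()[:16]
        annotations.append(LesionAnnotation(
            image_id=img.image_id,
            lesions=[(float(r), float(c), 1.0) for r, c in truth.ma_centroids]))
    write_annotations(out / "truth.csv", annotations)
    order = rng.permutation(n_images)
    half = n_images // 2
    train_ids = sorted(image_ids[i] for i in order[:half])
    test_ids = sorted(image_ids[i] for i in order[half:])
    manifest = {
        "n_images": n_images,
        "seed": seed,
        "spec": {**asdict(spec), "seed": None},
        "train": train_ids,
        "test": test_ids,
        "checksums": checksums,
        "n_lesions": sum(len(a.lesions) for a in annotations),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def sample_class_patches(img: FundusImage, truth: SceneTruth, i_clahe: np.ndarray,
                         rng: np.random.Generator, patch_size: int = 25,
                         n_vessel: int = 20, n_background: int = 20
                         ) -> dict[str, list[np.ndarray]]:
    """Cut I_CLAHE patches of the four structure classes (MA/HM/vessel/BG).

    MA and hemorrhage patches are centered on the planted lesions; vessel
    patches on random vessel-mask pixels; background patches on random
    FOV pixels clear of all structures.
    """
    from fundusma.candidates import cut_window

    half = patch_size // 2
    rows, cols = img.fov.shape
    inside = np.zeros_like(img.fov)
    inside[half:rows - half, half:cols - half] = True
    # keep whole windows inside the FOV so rays never hit the dark surround
    inside &= ndimage.binary_erosion(img.fov, iterations=half + 1)

    def _sample_mask(mask: np.ndarray, n: int) -> list[tuple[int, int]]:
        pts = np.argwhere(mask & inside & img.fov)
        if len(pts) == 0:
            return []
        idx = rng.choice(len(pts), size=min(n, len(pts)), replace=False)
        return [tuple(p) for p in pts[idx]]

    clear = ~ndimage.binary_dilation(
        truth.vessel_mask | truth.ma_mask | truth.hemorrhage_mask, iterations=15)
    centers = {
        "ma": [p for p in truth.ma_centroids if inside[p]],
        "hemorrhage": [p for p in truth.hemorrhage_centroids if inside[p]],
        "vessel": _sample_mask(truth.vessel_mask, n_vessel),
        "background": _sample_mask(clear, n_background),
    }
    return {cls: [cut_window(i_clahe, c, patch_size) for c in pts]
            for cls, pts in centers.items()}
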