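"""Run configuration: every tunable constant of the pipeline in one place.

The defaults are the published operating point of the method: a 50×50
median background window, CLAHE enhancement, Hessian scales σ ∈ {3..6},
slender-rejection multiplier 1.2, 500-px candidate area cap, 25×25
patches, and a 12-direction DLC descriptor of radius 12.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline parameters with their published / documented defaults."""

    # --- preprocessing ---
    median_size: int = 50          # background median window (odd-adjusted to 51)
    clahe_clip_limit: float = 0.05
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gauss_denoise_size: int = 7    # 7×7 Gaussian, sigma 1.0
    gauss_denoise_sigma: float = 1.0

    # --- FOV estimation ---
    fov_threshold_fraction: float = 0.06
    fov_erosion_px: int = 3

    # --- vessel segmentation ---
    vessel_sigmas: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0)
    min_vessel_region_area: float = 400.0   # px² at the reference FOV area
    # optional FOV-area rescaling of the cleanup cutoff (None = absolute px)
    reference_fov_area: float | None = None
    lambda_rho_scope: str = "per_scale"     # or "joint"

    # --- candidate extraction ---
    ratio_multiplier: float = 1.2
    max_candidate_area: int = 500
    contrast_stretch_mode: str = "minmax"   # or "percentile"

    # --- patches & features ---
    patch_size: int = 25
    dlc_radius: int = 12
    dlc_n_angles: int = 12
    dlc_interpolation: str = "nearest"      # or "bilinear"
    gaussian_bank_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)

    # --- classification ---
    classifier: str = "nb"                  # nb | knn | svm
    knn_k: int = 5
    svm_c: float = 1.0
    svm_gamma: float = 1.0 / 44.0

    # --- evaluation ---
    match_radius: float = 12.0
    min_confidence: float = 0.75
    fpi_grid: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

    # --- reproducibility ---
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in known:
                raise KeyError(f"unknown config key: {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
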