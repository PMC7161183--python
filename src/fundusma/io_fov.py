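"""Image / annotation I/O and field-of-view (FOV) estimation.

The FOV is the illuminated circular region of a fundus photograph; every
statistic downstream (background mean, Otsu histograms, stretch limits)
is computed inside it only.  All intensity processing is floating point
on [0, 1]; 8-bit conversion happens only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage


@dataclass
class FundusImage:
    """One eye image: 8-bit RGB raster, green plane on [0,1], FOV mask."""

    rgb: np.ndarray            # (rows, cols, 3) uint8
    green: np.ndarray          # (rows, cols) float64 in [0, 1]
    fov: np.ndarray            # (rows, cols) bool
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be a rows×cols×3 raster")
        if self.green.shape != self.rgb.shape[:2] or self.fov.shape != self.green.shape:
            raise ValueError("green/fov shape mismatch with rgb")
        if not self.fov.any():
            raise ValueError("FOV mask is empty")


@dataclass
class LesionAnnotation:
    """Ground-truth MA locations for one image.

    Each lesion is (row, col, confidence) with confidence the fraction of
    annotators that marked it (1.0 for a single-annotator source).
    """

    image_id: str
    lesions: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def centroids(self) -> np.ndarray:
        if not self.lesions:
            return np.empty((0, 2))
        return np.asarray([(r, c) for r, c, _ in self.lesions], dtype=float)


def estimate_fov(rgb: np.ndarray, threshold_fraction: float = 0.06,
                 erosion_px: int = 3) -> np.ndarray:
    """Estimate the FOV: largest bright component, hole-filled, eroded.

    Pixels whose mean-channel intensity exceeds ``threshold_fraction`` of
    full scale are foreground; the largest 4-connected component is kept,
    holes are filled, and the rim is eroded by ``erosion_px`` pixels to
    avoid the bright-edge artifacts common at the FOV boundary.

    Raises ``ValueError`` if the resulting mask is empty.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim == 3:
        mean_channel = arr.mean(axis=2)
    else:
        mean_channel = arr
    if mean_channel.max() > 1.0:      # 8-bit input
        mean_channel = mean_channel / 255.0
    fg = mean_channel > threshold_fraction
    if not fg.any():
        raise ValueError("FOV estimation failed: no pixel above threshold")
    labels, n = ndimage.label(fg)     # 4-connectivity (default structure)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    if erosion_px > 0:
        fg = ndimage.binary_erosion(fg, iterations=erosion_px, border_value=0)
    if not fg.any():
        raise ValueError("FOV estimation failed: mask empty after erosion")
    return fg


def load_fundus(path: str | Path, threshold_fraction: float = 0.06,
                erosion_px: int = 3) -> FundusImage:
    """Load a 3-channel image file, extract the green plane and FOV."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            rgb = np.asarray(im.convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"{path}: expected a 3-channel raster, got shape {rgb.shape}")
    try:
        fov = estimate_fov(rgb, threshold_fraction, erosion_px)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    green = rgb[:, :, 1].astype(np.float64) / 255.0
    return FundusImage(rgb=rgb, green=green, fov=fov, image_id=path.stem)


def fundus_from_array(rgb: np.ndarray, image_id: str = "",
                      threshold_fraction: float = 0.06,
                      erosion_px: int = 3) -> FundusImage:
    """Build a ``FundusImage`` from an in-memory uint8 RGB raster."""
    rgb = np.asarray(rgb)
    if rgb.dtype != np.uint8:
        raise ValueError("rgb array must be uint8")
    fov = estimate_fov(rgb, threshold_fraction, erosion_px)
    green = rgb[:, :, 1].astype(np.float64) / 255.0
    return FundusImage(rgb=rgb, green=green, fov=fov, image_id=image_id)


def read_annotations(path: str | Path, min_confidence: float = 0.0) -> list[LesionAnnotation]:
    """Read a lesion centroid CSV (``image_id,row,col,confidence``).

    Lesions with confidence below ``min_confidence`` are dropped; one
    ``LesionAnnotation`` is returned per image_id present (in file order).
    A missing confidence column defaults to 1.0 (single annotator).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    required = {"image_id", "row", "col"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns image_id,row,col[,confidence]")
    if "confidence" not in df.columns:
        df["confidence"] = 1.0
    for i, rec in df.iterrows():
        try:
            float(rec["row"]), float(rec["col"]), float(rec["confidence"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i + 2}: {list(rec)}") from exc
    df = df[df["confidence"].astype(float) >= min_confidence]
    out: list[LesionAnnotation] = []
    for image_id, grp in df.groupby("image_id", sort=False):
        lesions = [(float(r), float(c), float(cf))
                   for r, c, cf in zip(grp["row"], grp["col"], grp["confidence"])]
        out.append(LesionAnnotation(image_id=str(image_id), lesions=lesions))
    return out


def write_annotations(path: str | Path, annotations: list[LesionAnnotation]) -> None:
    rows = []
    for ann in annotations:
        for r, c, cf in ann.lesions:
            rows.append({"image_id": ann.image_id, "row": int(round(r)),
                         "col": int(round(c)), "confidence": cf})
    pd.DataFrame(rows, columns=["image_id", "row", "col", "confidence"]).to_csv(
        path, index=False)
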