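"""End-to-end orchestration: preprocess → vessels → candidates → features
→ classify → evaluate, driven by one ``RunConfig``.

``process_image`` runs the deterministic image-level stages once;
``run_train`` labels candidates against ground truth (same matching rule
as evaluation) and fits a classifier; ``run_detect`` scores candidates
and produces candidate-level ROC plus lesion-level FROC summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fundusma.candidates import (CandidatePatch, CandidateRegion, contrast_stretch,
                                 cut_patches, extract_candidates, remove_vessels)
from fundusma.classify import FittedModel, TrainingSet, save_model, score, train
from fundusma.config import RunConfig
from fundusma.evaluate import (CurveSummary, ScoredDetection, froc_curve,
                               match_lesions, roc_curve)
from fundusma.features import FEATURE_NAMES, extract_feature_matrix
from fundusma.io_fov import FundusImage, LesionAnnotation, load_fundus, read_annotations
from fundusma.preprocess import PreprocessedPlanes, preprocess_image
from fundusma.vessels import segment_vessels

log = logging.getLogger("fundusma")


@dataclass
class ImageResult:
    """Per-image stage outputs."""

    image_id: str
    planes: PreprocessedPlanes
    vessel_mask: np.ndarray
    regions: list[CandidateRegion]
    patches: list[CandidatePatch]
    features: np.ndarray                 # (n_candidates, 44)


def process_image(img: FundusImage, config: RunConfig) -> ImageResult:
    """Run the deterministic stages up to the feature matrix."""
    t0 = time.perf_counter()
    planes = preprocess_image(img, config.median_size, config.clahe_clip_limit,
                              tuple(config.clahe_tile_grid),
                              config.gauss_denoise_size, config.gauss_denoise_sigma)
    seg = segment_vessels(planes.i_sc, planes.fov, tuple(config.vessel_sigmas),
                          config.min_vessel_region_area, config.reference_fov_area,
                          config.lambda_rho_scope)
    i_gsbv0 = remove_vessels(planes.i_gauss, seg.mask)
    i_cs = contrast_stretch(i_gsbv0, planes.mean_green, planes.fov,
                            mode=config.contrast_stretch_mode)
    regions = extract_candidates(i_cs, planes.fov, config.ratio_multiplier,
                                 config.max_candidate_area)
    patches = cut_patches(planes, img.rgb, regions, config.patch_size)
    feats = extract_feature_matrix(patches, planes, config.dlc_radius,
                                   config.dlc_n_angles,
                                   tuple(config.gaussian_bank_sigmas))
    log.info("stage=process image_id=%s candidates=%d elapsed=%.2fs",
             img.image_id, len(regions), time.perf_counter() - t0)
    return ImageResult(image_id=img.image_id, planes=planes, vessel_mask=seg.mask,
                       regions=regions, patches=patches, features=feats)


def label_candidates(result: ImageResult, truth: LesionAnnotation,
                     match_radius: float) -> np.ndarray:
    """Binary labels: 1 where a candidate matches a ground-truth lesion."""
    dets = [ScoredDetection(region=r, score=1.0) for r in result.regions]
    m = match_lesions(dets, truth, threshold=0.0, match_radius=match_radius)
    labels = np.zeros(len(result.regions), dtype=int)
    for di, _ in m.tp_pairs:
        labels[di] = 1
    return labels


def _load_dataset(dataset_dir: str | Path, image_ids: list[str] | None,
                  config: RunConfig) -> tuple[list[FundusImage], dict[str, LesionAnnotation]]:
    dataset_dir = Path(dataset_dir)
    annotations = {a.image_id: a for a in read_annotations(dataset_dir / "truth.csv")}
    images = []
    for png in sorted(dataset_dir.glob("*.png")):
        if image_ids is not None and png.stem not in image_ids:
            continue
        images.append(load_fundus(png, config.fov_threshold_fraction,
                                  config.fov_erosion_px))
    return images, annotations


def run_train(dataset_dir: str | Path, config: RunConfig,
              image_ids: list[str] | None = None,
              model_out: str | Path | None = None) -> tuple[FittedModel, dict]:
    """Train a classifier on a benchmark directory (PNG images + truth.csv)."""
    images, annotations = _load_dataset(dataset_dir, image_ids, config)
    if not images:
        raise ValueError(f"no images found in {dataset_dir}")
    feats, labels, provenance = [], [], []
    for img in images:
        res = process_image(img, config)
        truth = annotations.get(img.image_id, LesionAnnotation(image_id=img.image_id))
        y = label_candidates(res, truth, config.match_radius)
        feats.append(res.features)
        labels.append(y)
        provenance.extend((img.image_id, r.label) for r in res.regions)
    x = np.vstack(feats)
    y = np.concatenate(labels)
    if y.sum() == 0:
        raise ValueError("no positive candidates matched ground truth; "
                         "use easier synthetic settings or a larger match radius")
    tset = TrainingSet(features=x, labels=y, provenance=provenance)
    fitted = train(tset, config.classifier, config.knn_k, config.svm_c, config.svm_gamma)
    manifest = {
        "model": config.classifier,
        "n_images": len(images),
        "n_candidates": int(y.size),
        "n_positive": int(y.sum()),
        "n_negative": int(y.size - y.sum()),
        "config": config.to_dict(),
    }
    if model_out is not None:
        save_model(fitted, model_out)
        Path(str(model_out) + ".manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return fitted, manifest


@dataclass
class DetectionReport:
    per_image: list[dict] = field(default_factory=list)
    roc: CurveSummary | None = None
    froc: CurveSummary | None = None
    detections: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        d: dict = {"per_image": self.per_image}
        if self.roc is not None:
            d["auc"] = self.roc.auc
            d["roc"] = self.roc.roc
        if self.froc is not None:
            d["froc_score"] = self.froc.froc_score
            d["froc"] = self.froc.froc
            d["sensitivity_at_fpi"] = {str(k): v for k, v in
                                       self.froc.sensitivity_at_fpi.items()}
        return d


def run_detect(dataset_dir: str | Path, config: RunConfig, fitted: FittedModel,
               image_ids: list[str] | None = None,
               evaluate_truth: bool = True) -> DetectionReport:
    """Score candidates on a dataset; evaluate against truth when present."""
    images, annotations = _load_dataset(dataset_dir, image_ids, config)
    if not images:
        raise ValueError(f"no images found in {dataset_dir}")
    report = DetectionReport()
    det_rows = []
    dets_per_image, truths_per_image = [], []
    pos_scores, neg_scores = [], []
    for img in images:
        res = process_image(img, config)
        s = score(fitted, res.features) if len(res.regions) else np.empty(0)
        dets = [ScoredDetection(region=r, score=float(v), classifier_id=config.classifier)
                for r, v in zip(res.regions, s)]
        truth = annotations.get(img.image_id, LesionAnnotation(image_id=img.image_id))
        dets_per_image.append(dets)
        truths_per_image.append(truth)
        for d in dets:
            det_rows.append({"image_id": img.image_id, "region_id": d.region.label,
                             "row": round(d.region.centroid[0], 2),
                             "col": round(d.region.centroid[1], 2),
                             "area": d.region.area, "score": round(d.score, 6)})
        if evaluate_truth:
            y = label_candidates(res, truth, config.match_radius)
            pos_scores.extend(s[y == 1].tolist())
            neg_scores.extend(s[y == 0].tolist())
            m = match_lesions(dets, truth, threshold=0.5,
                              match_radius=config.match_radius)
            report.per_image.append({"image_id": img.image_id, "tp": m.tp,
                                     "fp": m.fp, "fn": m.fn,
                                     "n_candidates": len(dets)})
    report.detections = pd.DataFrame(
        det_rows, columns=["image_id", "region_id", "row", "col", "area", "score"])
    if evaluate_truth and pos_scores and neg_scores:
        report.roc = roc_curve(np.asarray(pos_scores), np.asarray(neg_scores))
    if evaluate_truth and any(len(t.lesions) for t in truths_per_image):
        report.froc = froc_curve(dets_per_image, truths_per_image,
                                 config.match_radius, tuple(config.fpi_grid))
    return report
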