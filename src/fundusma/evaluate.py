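"""Lesion-level matching, ROC/AUC and FROC evaluation.

A detection counts as a true positive when its region contains a
ground-truth centroid or its own centroid lies within ``match_radius``
(default 12 px, half the patch size) of one; matching is one-to-one,
greedy by distance.  The FROC curve plots lesion sensitivity against
false positives per image (FPI); the FROC score is the mean sensitivity
interpolated at FPI ∈ {1/8, 1/4, 1/2, 1, 2, 4, 8}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics

from fundusma.candidates import CandidateRegion
from fundusma.io_fov import LesionAnnotation

FPI_GRID: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class ScoredDetection:
    region: CandidateRegion
    score: float
    classifier_id: str = "nb"


@dataclass
class LesionMatchResult:
    tp_pairs: list[tuple[int, int]]   # (detection index, truth index)
    fp_indices: list[int]
    fn_indices: list[int]

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_indices)

    @property
    def fn(self) -> int:
        return len(self.fn_indices)


@dataclass
class CurveSummary:
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    froc: list[tuple[float, float]] = field(default_factory=list)
    froc_score: float | None = None
    sensitivity_at_fpi: dict[float, float] = field(default_factory=dict)


def _detection_matches_truth(det: ScoredDetection, truth_rc: np.ndarray,
                             match_radius: float) -> tuple[bool, float]:
    """(matches?, distance) for one detection/truth pair."""
    tr, tc = truth_rc
    cy, cx = det.region.centroid
    dist = float(np.hypot(cy - tr, cx - tc))
    contains = bool(np.any((det.region.pixels[:, 0] == int(round(tr)))
                           & (det.region.pixels[:, 1] == int(round(tc)))))
    return (contains or dist <= match_radius), dist


def match_lesions(detections: list[ScoredDetection], truth: LesionAnnotation,
                  threshold: float = 0.5, match_radius: float = 12.0) -> LesionMatchResult:
    """One-to-one greedy-by-distance assignment at a score threshold."""
    active = [i for i, d in enumerate(detections) if d.score >= threshold]
    truths = truth.centroids
    pairs = []
    for di in active:
        for ti in range(len(truths)):
            ok, dist = _detection_matches_truth(detections[di], truths[ti], match_radius)
            if ok:
                pairs.append((dist, di, ti))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    tp_pairs = []
    for _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        tp_pairs.append((di, ti))
    fp = [di for di in active if di not in used_d]
    fn = [ti for ti in range(len(truths)) if ti not in used_t]
    return LesionMatchResult(tp_pairs=tp_pairs, fp_indices=fp, fn_indices=fn)


def roc_curve(scores_pos: np.ndarray, scores_neg: np.ndarray) -> CurveSummary:
    """Candidate-level ROC and trapezoid AUC from the two score samples."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both positive and negative score lists must be non-empty")
    y = np.concatenate([np.ones_like(scores_pos), np.zeros_like(scores_neg)])
    s = np.concatenate([scores_pos, scores_neg])
    fpr, tpr, _ = skmetrics.roc_curve(y, s)
    auc = float(skmetrics.auc(fpr, tpr))
    return CurveSummary(roc=list(zip(fpr.tolist(), tpr.tolist())), auc=auc)


def froc_curve(detections_per_image: list[list[ScoredDetection]],
               truths_per_image: list[LesionAnnotation],
               match_radius: float = 12.0,
               fpi_grid: tuple[float, ...] = FPI_GRID) -> CurveSummary:
    """Lesion-level FROC over a threshold sweep of all detection scores.

    Sensitivities are linearly interpolated at the grid FPI values;
    right-constant above the largest achieved FPI, zero below the
    smallest.  Raises if there are no ground-truth lesions at all.
    """
    n_images = len(detections_per_image)
    if n_images < 1 or len(truths_per_image) != n_images:
        raise ValueError("need one truth annotation per image")
    n_truths = sum(len(t.lesions) for t in truths_per_image)
    if n_truths == 0:
        raise ValueError("FROC undefined with zero ground-truth lesions")
    all_scores = np.concatenate([
        np.asarray([d.score for d in dets], dtype=float) if dets else np.empty(0)
        for dets in detections_per_image
    ]) if any(detections_per_image) else np.empty(0)
    thresholds = np.unique(all_scores)[::-1]     # descending; ties = one step
    # precompute matching pairs per image; the greedy assignment per
    # threshold then runs on these small lists only
    per_image = []
    for dets, truth in zip(detections_per_image, truths_per_image):
        truths = truth.centroids
        pairs = []
        for di, d in enumerate(dets):
            for ti in range(len(truths)):
                ok, dist = _detection_matches_truth(d, truths[ti], match_radius)
                if ok:
                    pairs.append((dist, di, ti))
        pairs.sort(key=lambda t: (t[0], t[1], t[2]))
        scores = np.asarray([d.score for d in dets], dtype=float)
        per_image.append((scores, pairs))
    points = []
    for thr in thresholds:
        tp = fp = 0
        for scores, pairs in per_image:
            n_active = int((scores >= thr).sum())
            used_d: set[int] = set()
            used_t: set[int] = set()
            for _, di, ti in pairs:
                if scores[di] < thr or di in used_d or ti in used_t:
                    continue
                used_d.add(di)
                used_t.add(ti)
            tp += len(used_d)
            fp += n_active - len(used_d)
        points.append((fp / n_images, tp / n_truths))
    points.sort(key=lambda p: (p[0], p[1]))
    if points:
        fpi = np.asarray([p[0] for p in points])
        sens = np.asarray([p[1] for p in points])
        sens = np.maximum.accumulate(sens)       # staircase: best sens at each FPI
        at_grid = np.interp(fpi_grid, fpi, sens, left=0.0, right=float(sens[-1]))
    else:
        at_grid = np.zeros(len(fpi_grid))
    froc_score = float(np.mean(at_grid))
    return CurveSummary(froc=points, froc_score=froc_score,
                        sensitivity_at_fpi=dict(zip(fpi_grid, at_grid.tolist())))
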