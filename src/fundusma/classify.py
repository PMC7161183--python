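"""Candidate-patch classification: Gaussian naive Bayes, KNN, SVM-RBF.

All three classifiers run on z-score-standardized 44-feature vectors and
emit a continuous MA score in [0, 1] so a single threshold sweep yields
both ROC and FROC curves.  Naive Bayes and KNN scores are posterior
probabilities; the SVM score is the logistic squash of the decision
function (deterministic, unlike Platt scaling with internal CV).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from fundusma.features import FEATURE_NAMES

MODEL_FORMAT_VERSION = 1


def feature_schema_checksum(names: tuple[str, ...] = FEATURE_NAMES) -> str:
    return hashlib.sha256("|".join(names).encode()).hexdigest()[:16]


@dataclass
class TrainingSet:
    """Standardization-aware training set with per-sample provenance."""

    features: np.ndarray                 # (n_samples, 44)
    labels: np.ndarray                   # binary, 1 = MA
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features/labels length mismatch")


@dataclass
class FittedModel:
    model_name: str                      # nb | knn | svm
    scaler: StandardScaler
    estimator: object
    schema_checksum: str = field(default_factory=feature_schema_checksum)
    version: int = MODEL_FORMAT_VERSION


def train(tset: TrainingSet, model: str = "nb", knn_k: int = 5,
          svm_c: float = 1.0, svm_gamma: float | str = 1.0 / 44.0,
          n_features_expected: int | None = 44) -> FittedModel:
    """Fit one of the three classifiers on standardized features.

    Requires both classes present.  ``n_features_expected=None`` disables
    the dimensionality check (useful for toy problems in tests).
    """
    x, y = tset.features, tset.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    if n_features_expected is not None and x.shape[1] != n_features_expected:
        raise ValueError(f"expected {n_features_expected} features, got {x.shape[1]}")
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    if model == "nb":
        est = GaussianNB(var_smoothing=1e-9).fit(xs, y)
    elif model == "knn":
        est = KNeighborsClassifier(n_neighbors=knn_k, metric="euclidean").fit(xs, y)
    elif model == "svm":
        est = SVC(C=svm_c, gamma=svm_gamma, kernel="rbf").fit(xs, y)
    else:
        raise ValueError(f"unknown model {model!r} (use nb|knn|svm)")
    checksum = (feature_schema_checksum() if x.shape[1] == len(FEATURE_NAMES)
                else hashlib.sha256(f"adhoc-{x.shape[1]}".encode()).hexdigest()[:16])
    return FittedModel(model_name=model, scaler=scaler, estimator=est,
                       schema_checksum=checksum)


def score(fitted: FittedModel, features: np.ndarray) -> np.ndarray:
    """MA score in [0, 1] per feature row; deterministic for a fitted model."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != fitted.scaler.mean_.shape[0]:
        raise ValueError(f"feature count {x.shape[1]} does not match the "
                         f"model ({fitted.scaler.mean_.shape[0]})")
    xs = fitted.scaler.transform(x)
    est = fitted.estimator
    if fitted.model_name == "svm":
        d = est.decision_function(xs)
        if est.classes_[1] != 1:     # ensure the score tracks the MA class
            d = -d
        s = 1.0 / (1.0 + np.exp(-d))
    else:
        proba = est.predict_proba(xs)
        pos_col = int(np.nonzero(est.classes_ == 1)[0][0])
        s = proba[:, pos_col]
    return np.clip(s, 0.0, 1.0)


def save_model(fitted: FittedModel, path) -> None:
    joblib.dump({
        "version": fitted.version,
        "model_name": fitted.model_name,
        "schema_checksum": fitted.schema_checksum,
        "scaler": fitted.scaler,
        "estimator": fitted.estimator,
    }, path)


def load_model(path, expect_schema: bool = True) -> FittedModel:
    blob = joblib.load(path)
    if blob.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version: {blob.get('version')}")
    fitted = FittedModel(model_name=blob["model_name"], scaler=blob["scaler"],
                         estimator=blob["estimator"],
                         schema_checksum=blob["schema_checksum"])
    if expect_schema and fitted.schema_checksum != feature_schema_checksum():
        raise ValueError("model feature schema does not match this package version")
    return fitted
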