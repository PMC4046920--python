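"""Two-stage SVM-RBF classification of focus candidates.

Stage 1 separates true foci from noise (spurious intensity domes); stage 2
separates large bright foci (clonally expanded events) from small irregular
foci. Both stages are binary RBF-kernel support vector machines trained on
annotated feature vectors with per-feature standardization and stratified
cross-validated grid search over (C, γ).

A *conservative* mode raises the stage-1 decision threshold by a stored
offset so that, at the cost of false negatives, essentially no noise
candidate is accepted — counting only foci with consistent morphology and
intensity. Avoiding false positives matters more than avoiding false
negatives for frequency estimates near the spontaneous rate.

Models serialize to a versioned JSON schema (kernel parameters, support
vectors, dual coefficients, intercept, standardization statistics) and
predict through an explicit kernel sum, so a saved model is readable and
usable without any training-environment pickle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .segment import FEATURE_NAMES

__all__ = [
    "StageSVM",
    "TwoStageClassifier",
    "train_stage",
    "save_model",
    "load_model",
    "LABEL_NOISE",
    "LABEL_SMALL",
    "LABEL_LARGE",
]

LABEL_NOISE = "noise"
LABEL_SMALL = "small_focus"
LABEL_LARGE = "large_focus"

SCHEMA_VERSION = 1

DEFAULT_GRID = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [0.01, 0.1, 1.0, 10.0]}


@dataclass
class StageSVM:
    """One binary RBF-SVM stage with its standardization, as plain arrays.

    ``decision(X) > 0`` predicts ``positive_label``. Prediction is an
    explicit kernel sum Σ αᵢ K(svᵢ, x) + intercept over standardized
    features and is deterministic.
    """

    stage: str  # "noise-vs-focus" | "small-vs-large"
    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    gamma: float
    C: float
    support_vectors: np.ndarray  # standardized feature space
    dual_coef: np.ndarray  # signed alpha_i * y_i
    intercept: float
    negative_label: str
    positive_label: str
    cv_accuracy: float = float("nan")

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale

    def decision(self, X: np.ndarray) -> np.ndarray:
        """RBF kernel-sum decision function on raw (unstandardized) features."""
        Z = self._standardize(np.asarray(X, dtype=float))
        d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return (self.dual_coef * np.exp(-self.gamma * d2)).sum(axis=1) + self.intercept

    def predict(self, X: np.ndarray, threshold_offset: float = 0.0) -> np.ndarray:
        d = self.decision(X)
        return np.where(d > threshold_offset, self.positive_label, self.negative_label)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "gamma": self.gamma,
            "C": self.C,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "negative_label": self.negative_label,
            "positive_label": self.positive_label,
            "cv_accuracy": self.cv_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageSVM":
        return cls(
            stage=d["stage"],
            feature_names=list(d["feature_names"]),
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            gamma=float(d["gamma"]),
            C=float(d["C"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            negative_label=d["negative_label"],
            positive_label=d["positive_label"],
            cv_accuracy=float(d.get("cv_accuracy", float("nan"))),
        )


def _feature_matrix(features: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    for name in names:
        if name not in features.columns:
            raise KeyError(f"missing feature column: {name!r}")
    return features[list(names)].to_numpy(dtype=float)


def train_stage(
    annotations: pd.DataFrame,
    stage: str,
    grid: Optional[dict] = None,
    cv_folds: int = 5,
    seed: int = 0,
    feature_names: Sequence[str] = tuple(FEATURE_NAMES),
) -> StageSVM:
    """Train one binary stage from an annotation table.

    ``annotations`` holds the feature columns plus a ``label`` column with
    values in {noise, small_focus, large_focus}. Stage ``"noise-vs-focus"``
    maps both focus classes to "focus"; stage ``"small-vs-large"`` uses the
    focus rows only. (C, γ) are selected by stratified ``cv_folds``-fold
    cross-validation over ``grid`` on standardized features; deterministic
    given the fold seed.
    """
    grid = grid or DEFAULT_GRID
    if stage == "noise-vs-focus":
        y = np.where(annotations["label"] == LABEL_NOISE, LABEL_NOISE, "focus")
        df = annotations
        neg, pos = LABEL_NOISE, "focus"
    elif stage == "small-vs-large":
        df = annotations[annotations["label"] != LABEL_NOISE]
        y = df["label"].to_numpy()
        neg, pos = LABEL_SMALL, LABEL_LARGE
    else:
        raise ValueError(f"unknown stage {stage!r}")

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"stage {stage!r} needs two classes, got {list(classes)}")
    if counts.min() < cv_folds:
        raise ValueError(
            f"stage {stage!r}: smallest class has {counts.min()} examples, "
            f"fewer than {cv_folds} folds"
        )

    X = _feature_matrix(df, feature_names)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pipe = Pipeline([("scaler", StandardScaler()), ("svc", SVC(kernel="rbf"))])
    search = GridSearchCV(
        pipe,
        {"svc__C": grid["C"], "svc__gamma": grid["gamma"]},
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(X, y)
    scaler: StandardScaler = search.best_estimator_.named_steps["scaler"]
    svc: SVC = search.best_estimator_.named_steps["svc"]

    # orient the decision function so that decision > 0 <=> positive_label
    sk_neg, sk_pos = svc.classes_  # sklearn: decision > 0 -> classes_[1]
    flip = 1.0 if sk_pos == pos else -1.0
    return StageSVM(
        stage=stage,
        feature_names=list(feature_names),
        mean=scaler.mean_.copy(),
        scale=scaler.scale_.copy(),
        gamma=float(svc._gamma) if hasattr(svc, "_gamma") else float(svc.gamma),
        C=float(svc.C),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=flip * svc.dual_coef_[0].copy(),
        intercept=flip * float(svc.intercept_[0]),
        negative_label=neg,
        positive_label=pos,
        cv_accuracy=float(search.best_score_),
    )


@dataclass
class TwoStageClassifier:
    """Sequential classifier: noise-vs-focus, then small-vs-large.

    ``conservative_offset`` shifts the stage-1 decision threshold upward in
    conservative mode; candidates classified noise in stage 1 never reach
    stage 2.
    """

    stage1: StageSVM
    stage2: StageSVM
    conservative_offset: float = 0.0

    def predict(self, features: pd.DataFrame, conservative: bool = False) -> np.ndarray:
        X1 = _feature_matrix(features, self.stage1.feature_names)
        offset = self.conservative_offset if conservative else 0.0
        d1 = self.stage1.decision(X1)
        labels = np.full(len(features), LABEL_NOISE, dtype=object)
        is_focus = d1 > offset
        if is_focus.any():
            X2 = _feature_matrix(features.loc[is_focus], self.stage2.feature_names)
            labels[is_focus] = self.stage2.predict(X2)
        return labels.astype(str)


def save_model(model: TwoStageClassifier, path: str | Path) -> None:
    """Serialize to the versioned JSON schema."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "model_type": "two-stage-svm-rbf",
        "conservative_offset": model.conservative_offset,
        "stage1": model.stage1.to_dict(),
        "stage2": model.stage2.to_dict(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TwoStageClassifier:
    """Load a model saved by :func:`save_model`.

    Raises ``ValueError`` on a truncated/corrupt file or a schema-version
    mismatch.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupt or truncated model file {path}: {e}") from None
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version!r} unsupported (expected {SCHEMA_VERSION})"
        )
    return TwoStageClassifier(
        stage1=StageSVM.from_dict(payload["stage1"]),
        stage2=StageSVM.from_dict(payload["stage2"]),
        conservative_offset=float(payload.get("conservative_offset", 0.0)),
    )
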