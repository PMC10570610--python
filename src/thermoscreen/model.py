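"""The 3-feature linear screening classifier.

A screening (rule-out) test must rarely miss malignancy, so the decision
threshold is tuned for sensitivity rather than accuracy: after fitting an
unregularized logistic score s = w.x + b on the training cohort, the
threshold is set to the largest value that still achieves a training
sensitivity of at least ``min_sensitivity`` (default 0.85).  Everything a
prediction needs — the three selected features, weights, bias, threshold and
the training normalization statistics — is frozen into :class:`LinearModel`,
so validation is a genuinely fixed algorithm.

Leave-one-out cross-validation refits the *entire* pipeline (normalization,
feature selection, weights, threshold) on each n-1 subset, avoiding any
information leakage from the held-out lesion.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, TrainingError
from .features import (
    DOG_COL,
    LABEL_COL,
    NormalizationStats,
    normalize,
    select_features,
)
from .metrics import ConfusionMatrix
from .simulate import MALIGNANT

LABEL_POSITIVE = "requires_further_investigation"
LABEL_NEGATIVE = "benign"


@dataclass(frozen=True)
class TrainConfig:
    min_sensitivity: float = 0.85
    n_features: int = 3
    group_by_dog: bool = False  # leave-one-dog-out instead of leave-one-lesion-out
    max_iter: int = 10000
    tol: float = 1e-8


@dataclass
class LinearModel:
    """Frozen linear screening model (weights + threshold + normalization)."""

    feature_ids: List[str]
    weights: np.ndarray
    bias: float
    threshold: float
    normalization: NormalizationStats
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.feature_ids) != len(self.weights):
            raise ConfigurationError("one weight per feature required")
        for f in self.feature_ids:
            if f not in self.normalization.features:
                raise ConfigurationError(f"feature {f!r} missing from normalization stats")
        if not (
            np.all(np.isfinite(self.weights))
            and math.isfinite(self.bias)
            and math.isfinite(self.threshold)
        ):
            raise ConfigurationError("weights, bias and threshold must be finite")

    def score(self, features: pd.DataFrame) -> np.ndarray:
        """Linear score w.x + b on raw features (stored stats applied)."""
        missing = [f for f in self.feature_ids if f not in features.columns]
        if missing:
            raise ConfigurationError(f"missing features: {missing}")
        z, _ = normalize(features, self.normalization)
        x = z[self.feature_ids].to_numpy(dtype=float)
        return x @ self.weights + self.bias

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "feature_ids": list(self.feature_ids),
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "threshold": float(self.threshold),
            "normalization": self.normalization.to_dict(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            feature_ids=list(d["feature_ids"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            threshold=float(d["threshold"]),
            normalization=NormalizationStats.from_dict(d["normalization"]),
            metadata=dict(d.get("metadata", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "LinearModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _labels(table: pd.DataFrame) -> np.ndarray:
    return (table[LABEL_COL] == MALIGNANT).to_numpy(dtype=int)


def sensitivity_threshold(scores: np.ndarray, y: np.ndarray, min_sensitivity: float) -> float:
    """Screening threshold: maximize specificity subject to a sensitivity floor.

    A lesion is flagged when score >= threshold.  Among candidate thresholds
    (the observed scores) achieving training sensitivity >= min_sensitivity,
    the one with the highest specificity is chosen; ties are broken toward
    higher sensitivity (the lower threshold).  On a separable score set this
    yields 100% sensitivity and specificity; in general it gives the best
    rule-out specificity compatible with the sensitivity floor.  The floor is
    always attainable — a threshold at the minimum score flags everything.
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0:
        raise TrainingError("no positive-class lesions to tune the threshold on")
    candidates = np.unique(scores)
    best: tuple[float, float, float] | None = None  # (spec, sens, thr)
    for thr in candidates:
        sens = float(np.mean(pos >= thr))
        if sens < min_sensitivity - 1e-12:
            continue
        spec = float(np.mean(neg < thr)) if len(neg) else 1.0
        if best is None or (spec, sens) > (best[0], best[1]):
            best = (spec, sens, float(thr))
    if best is None:  # floor unattainable among candidates: fall back to flag-all
        return float(candidates.min())
    return best[2]


def train(table: pd.DataFrame, config: TrainConfig = TrainConfig()) -> LinearModel:
    """Fit the full screening pipeline on a raw feature table.

    Fits normalization statistics, selects ``n_features`` features by
    point-biserial ranking, fits an unregularized logistic score with a
    deterministic lbfgs optimizer, and tunes the screening threshold.
    """
    y = _labels(table)
    if len(np.unique(y)) < 2:
        raise TrainingError("training table must contain both classes")
    z, stats = normalize(table)
    selected = select_features(z, k=config.n_features)
    x = z[selected].to_numpy(dtype=float)

    # C=inf => unregularized; lbfgs is deterministic for a fixed input
    clf = LogisticRegression(
        C=np.inf, solver="lbfgs", tol=config.tol, max_iter=config.max_iter
    )
    clf.fit(x, y)
    w = clf.coef_.ravel()
    b = float(clf.intercept_[0])
    if not (np.all(np.isfinite(w)) and math.isfinite(b)):
        raise TrainingError(f"logistic fit diverged: w={w}, b={b}")

    scores = x @ w + b
    threshold = sensitivity_threshold(scores, y, config.min_sensitivity)
    return LinearModel(
        feature_ids=selected,
        weights=w,
        bias=b,
        threshold=threshold,
        normalization=stats,
        metadata={
            "n_train": int(len(table)),
            "min_sensitivity": config.min_sensitivity,
            "converged": bool(clf.n_iter_[0] < config.max_iter),
        },
    )


def predict(model: LinearModel, features: pd.DataFrame) -> pd.DataFrame:
    """Score lesions and label them; score >= threshold flags the mass.

    A score exactly at the threshold is flagged for further investigation —
    the conservative choice for a rule-out test.
    """
    scores = model.score(features)
    labels = np.where(scores >= model.threshold, LABEL_POSITIVE, LABEL_NEGATIVE)
    return pd.DataFrame({"score": scores, "label": labels}, index=features.index)


def confusion_from_predictions(pred: pd.DataFrame, table: pd.DataFrame) -> ConfusionMatrix:
    y_true = _labels(table)
    y_pred = (pred.loc[table.index, "label"] == LABEL_POSITIVE).to_numpy(dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def evaluate_fixed(
    model: LinearModel, table: pd.DataFrame
) -> Tuple[ConfusionMatrix, pd.DataFrame]:
    """Apply a frozen model to a labelled table; no refitting of any kind."""
    pred = predict(model, table)
    return confusion_from_predictions(pred, table), pred


def loo_cross_validate(
    table: pd.DataFrame, config: TrainConfig = TrainConfig()
) -> Tuple[ConfusionMatrix, pd.DataFrame]:
    """Leave-one-out evaluation with the whole pipeline inside each fold.

    For every held-out unit (lesion by default, dog with
    ``config.group_by_dog``) the normalization statistics, feature selection,
    logistic weights and screening threshold are refit on the remaining
    lesions, and the held-out lesions are scored with those frozen
    parameters.  Folds whose training half loses one class entirely are
    flagged and excluded from the matrix.
    """
    if len(table) < 10:
        raise ConfigurationError("leave-one-out needs at least 10 lesions")
    y_all = _labels(table)
    if len(np.unique(y_all)) < 2:
        raise TrainingError("both classes required")

    if config.group_by_dog:
        groups = table[DOG_COL].to_numpy()
    else:
        groups = table.index.to_numpy()
    unique_groups = pd.unique(groups)

    rows = []
    for g in unique_groups:
        hold = groups == g
        train_tab = table.loc[~hold]
        if len(np.unique(_labels(train_tab))) < 2:
            for lesion in table.index[hold]:
                rows.append({"lesion_id": lesion, "score": np.nan, "label": None, "flagged": True})
            continue
        fold_model = train(train_tab, config)
        pred = predict(fold_model, table.loc[hold])
        for lesion, (score, label) in zip(pred.index, pred.itertuples(index=False)):
            rows.append({"lesion_id": lesion, "score": score, "label": label, "flagged": False})

    preds = pd.DataFrame(rows).set_index("lesion_id").loc[table.index]
    ok = ~preds["flagged"]
    cm = confusion_from_predictions(preds.loc[ok], table.loc[ok])
    return cm, preds


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
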