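"""Per-metric emotion classifiers and the accuracy-weighted combined model.

Each of the three triad metrics (structure, color, texture) gets its own
classifier trained on expressive faces; its held-out test accuracy then
becomes its weight in the combined model, whose output for class *j* is

    combined_j = sum_m w_m * I_mj / sum_m w_m

with ``w_m`` the metric accuracies, renormalised so the result stays on the
probability simplex.  The default base learner is a regularised multinomial
logistic regression (standardised inputs); a config hook switches to
gradient-boosted trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from facetriad import EMOTIONS


@dataclass
class LearnerConfig:
    """Base-learner configuration for the metric models."""

    kind: str = "logistic"  # "logistic" | "gbm"
    C: float = 1.0
    max_iter: int = 2000
    test_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("logistic", "gbm"):
            raise ValueError(f"unknown learner kind {self.kind!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class MetricModel:
    """A fitted classifier for one metric plus its held-out accuracy."""

    metric: str
    estimator: Pipeline
    test_accuracy: float
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.test_accuracy <= 1.0:
            raise ValueError("test_accuracy must lie in [0, 1]")


@dataclass
class CombinedModel:
    """The accuracy-weighted ensemble of the three metric models."""

    models: dict[str, MetricModel]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weights:
            self.weights = {m: mod.test_accuracy for m, mod in self.models.items()}
        if any(w < 0 or w > 1 for w in self.weights.values()):
            raise ValueError("weights must lie in [0, 1]")
        if sum(self.weights.values()) <= 0:
            raise ValueError("at least one weight must be positive")

    def predict(self, features: dict[str, pd.DataFrame]) -> pd.DataFrame:
        outputs = {m: predict(self.models[m], features[m]) for m in self.models}
        first = next(iter(outputs.values()))
        combined = combine_weighted(
            [outputs[m].loc[first.index] for m in self.models],
            [self.weights[m] for m in self.models],
        )
        combined.index = first.index
        return combined


def split_train_test(
    metadata: pd.DataFrame, test_fraction: float, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Disjoint train/test face-id lists, stratified by emotion x gender."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    strata = metadata["emotion"].astype(str) + "|" + metadata["gender"].astype(str)
    if strata.value_counts().min() < 2:
        raise ValueError("every emotion x gender stratum needs at least 2 faces")
    train_ids, test_ids = train_test_split(
        metadata["face_id"].to_numpy(),
        test_size=test_fraction,
        stratify=strata,
        random_state=seed,
    )
    return sorted(train_ids), sorted(test_ids)


def _make_estimator(config: LearnerConfig, seed: int) -> Pipeline:
    if config.kind == "gbm":
        clf = HistGradientBoostingClassifier(random_state=seed)
    else:
        clf = LogisticRegression(C=config.C, max_iter=config.max_iter, random_state=seed)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_metric_model(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    learner_config: LearnerConfig | None = None,
    seed: int = 0,
    metric: str = "structure",
) -> MetricModel:
    """Fit one metric's classifier and score it on an internal held-out set.

    The held-out set is a stratified ``test_fraction`` split of the rows;
    test faces never enter the fit, which is what makes the accuracy a valid
    ensemble weight.
    """
    config = learner_config or LearnerConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("features and labels must have the same length")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=config.test_fraction, stratify=y, random_state=seed
    )
    est = _make_estimator(config, seed)
    est.fit(X_tr, y_tr)
    acc = float(np.mean(est.predict(X_te) == y_te))
    classes = tuple(c for c in EMOTIONS if c in est.named_steps["clf"].classes_)
    return MetricModel(metric=metric, estimator=est, test_accuracy=acc, classes=classes)


def predict(model: MetricModel, features: pd.DataFrame) -> pd.DataFrame:
    """Per-face emotion probabilities in the canonical class order."""
    X = np.asarray(features, dtype=float)
    n_expected = model.estimator.named_steps["scale"].n_features_in_
    if X.shape[1] != n_expected:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} does not match training ({n_expected})"
        )
    proba = model.estimator.predict_proba(X)
    fitted = list(model.estimator.named_steps["clf"].classes_)
    out = pd.DataFrame(0.0, index=getattr(features, "index", range(len(X))),
                       columns=list(EMOTIONS))
    for j, cls in enumerate(fitted):
        out[cls] = proba[:, j]
    return out


def combine_weighted(
    outputs: list[pd.DataFrame | np.ndarray], weights: list[float]
) -> pd.DataFrame:
    """Accuracy-weighted sum of per-metric emotion outputs, renormalised."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    mats = []
    columns = list(EMOTIONS)
    for out in outputs:
        if isinstance(out, pd.DataFrame):
            if list(out.columns) != columns:
                out = out[columns]
            mats.append(out.to_numpy(dtype=float))
        else:
            mats.append(np.atleast_2d(np.asarray(out, dtype=float)))
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("emotion outputs must share shape and class order")
    combined = sum(wi * m for wi, m in zip(w, mats)) / w.sum()
    return pd.DataFrame(combined, columns=columns)


def evaluate_accuracy(
    model: MetricModel, features: pd.DataFrame, labels: pd.Series | np.ndarray
) -> dict:
    """Overall accuracy, per-class accuracies, and the confusion table."""
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("test set is empty")
    unseen = set(np.unique(y)) - set(EMOTIONS)
    if unseen:
        raise ValueError(f"unseen class labels in test set: {sorted(unseen)}")
    proba = predict(model, features)
    pred = proba.to_numpy().argmax(axis=1)
    pred_labels = np.asarray(EMOTIONS)[pred]
    classes = [c for c in EMOTIONS if c in set(y) | set(pred_labels)]
    conf = confusion_matrix(y, pred_labels, labels=classes)
    overall = float(np.mean(pred_labels == y))
    per_class = {
        c: float(conf[i, i] / conf[i].sum()) if conf[i].sum() else np.nan
        for i, c in enumerate(classes)
    }
    return {
        "overall": overall,
        "per_class": per_class,
        "confusion": pd.DataFrame(conf, index=classes, columns=classes),
    }


def train_combined(
    features: dict[str, pd.DataFrame],
    labels: pd.Series | np.ndarray,
    learner_config: LearnerConfig | None = None,
    seed: int = 0,
) -> CombinedModel:
    """Train all three metric models on aligned feature tables."""
    models = {
        m: train_metric_model(features[m], labels, learner_config, seed=seed, metric=m)
        for m in features
    }
    return CombinedModel(models=models)
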