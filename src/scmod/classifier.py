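"""Feed-forward subtype classifier, vote aggregation, and evaluation.

A small fully connected network (ReLU hidden layers, softmax output,
categorical cross-entropy, SGD with early stopping) is trained on the
perturbation feature vectors. Because the feature dimension (T*E)
typically dwarfs the number of training samples, a single SGD run is
sensitive to its weight initialization; the classifier therefore fits
a small ensemble of identically configured networks from different
initializations and averages their softmax outputs. At prediction
time a sample's vectors — one per reference set — each cast a vote;
the modal class wins, ties broken by mean softmax probability then
class order.

Macro-averaged metrics are used throughout because the subtype sizes
are imbalanced: macro-P and macro-R average per-class precision and
recall uniformly, and macro-F1 is the harmonic mean of macro-P and
macro-R (not the mean of per-class F1 scores).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    hidden_sizes: tuple = (50, 10)
    learning_rate: float = 0.1
    batch_size: int = 32
    max_epochs: int = 500
    early_stop_patience: int = 20
    validation_fraction: float = 0.1
    n_members: int = 5
    seed: int = 0

    def __post_init__(self):
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.n_members < 1:
            raise ValueError("need at least one ensemble member")


def cross_entropy(proba: np.ndarray, y_onehot: np.ndarray) -> float:
    """Mean categorical cross-entropy -1/N sum_i sum_c y_ic log p_ic."""
    p = np.clip(np.asarray(proba, float), 1e-300, 1.0)
    return float(-(np.asarray(y_onehot) * np.log(p)).sum() / len(p))


@dataclass
class SubtypeClassifier:
    """Trained MLP ensemble with a self-contained forward pass.

    ``members`` holds one (coefs, intercepts) weight list per ensemble
    member; predicted probabilities are the members' mean softmax.
    Weights are kept as plain arrays so models serialize to JSON and
    prediction does not depend on the training backend.
    """

    classes_: list
    members: list
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    @staticmethod
    def _forward(X: np.ndarray, coefs, intercepts) -> np.ndarray:
        a = X
        for w, b in zip(coefs[:-1], intercepts[:-1]):
            a = np.maximum(a @ w + b, 0.0)  # ReLU hidden layers
        z = a @ coefs[-1] + intercepts[-1]
        if z.shape[1] == 1:  # binary case: single logistic output unit
            p = 1.0 / (1.0 + np.exp(-z[:, 0]))
            return np.column_stack([1.0 - p, p])
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        probs = [self._forward(X, c, i) for c, i in self.members]
        return np.mean(probs, axis=0)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.asarray(self.classes_)[proba.argmax(axis=1)]

    def to_json(self, path) -> None:
        payload = {
            "classes": list(self.classes_),
            "members": [
                {
                    "coefs": [w.tolist() for w in coefs],
                    "intercepts": [b.tolist() for b in intercepts],
                }
                for coefs, intercepts in self.members
            ],
            "config": {
                "hidden_sizes": list(self.config.hidden_sizes),
                "learning_rate": self.config.learning_rate,
                "batch_size": self.config.batch_size,
                "max_epochs": self.config.max_epochs,
                "early_stop_patience": self.config.early_stop_patience,
                "validation_fraction": self.config.validation_fraction,
                "n_members": self.config.n_members,
                "seed": self.config.seed,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SubtypeClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        members = [
            (
                [np.array(w) for w in m["coefs"]],
                [np.array(b) for b in m["intercepts"]],
            )
            for m in payload["members"]
        ]
        return cls(
            classes_=payload["classes"], members=members,
            config=ClassifierConfig(**cfg),
        )


def _split_xy(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "label" not in features.columns:
        raise ValueError("feature frame has no label column")
    X = features.drop(columns="label").to_numpy(float)
    y = features["label"].to_numpy()
    return X, y


def train(features: pd.DataFrame, cfg: ClassifierConfig | None = None) -> SubtypeClassifier:
    """Fit the MLP on a labeled feature frame; deterministic given seed."""
    if cfg is None:
        cfg = ClassifierConfig()
    X, y = _split_xy(features)
    if len(set(y)) < 2:
        raise ValueError("training data contains a single class")
    members = []
    classes = None
    for m in range(cfg.n_members):
        mlp = MLPClassifier(
            hidden_layer_sizes=tuple(cfg.hidden_sizes),
            activation="relu",
            solver="sgd",
            learning_rate_init=cfg.learning_rate,
            batch_size=cfg.batch_size,
            max_iter=cfg.max_epochs,
            early_stopping=True,
            n_iter_no_change=cfg.early_stop_patience,
            validation_fraction=cfg.validation_fraction,
            random_state=(cfg.seed + m) & 0x7FFFFFFF,
        )
        mlp.fit(X, y)
        if classes is None:
            classes = list(mlp.classes_)
        members.append(
            (
                [np.array(w) for w in mlp.coefs_],
                [np.array(b) for b in mlp.intercepts_],
            )
        )
    return SubtypeClassifier(classes_=classes, members=members, config=cfg)


def predict_vote(model: SubtypeClassifier, sample_features: pd.DataFrame | np.ndarray):
    """Majority vote over a sample's feature vectors.

    Each vector votes its argmax class; the modal class wins. Ties go
    to the tied class with the highest mean softmax probability, then
    to class order. Returns (label, n_votes_for_winner).
    """
    if isinstance(sample_features, pd.DataFrame):
        X = sample_features.drop(columns="label", errors="ignore").to_numpy(float)
    else:
        X = np.atleast_2d(np.asarray(sample_features, float))
    if len(X) == 0:
        raise ValueError("no feature vectors for sample")
    proba = model.predict_proba(X)
    votes = proba.argmax(axis=1)
    counts = Counter(votes)
    top = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == top)
    if len(tied) > 1:
        mean_p = proba.mean(axis=0)
        best = max(tied, key=lambda c: (mean_p[c], -c))
    else:
        best = tied[0]
    return model.classes_[best], int(counts[best])


def predict_samples(model: SubtypeClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Vote-aggregate predictions for every sample_id in a feature frame."""
    out = []
    for sid, block in features.groupby(level="sample_id", sort=True):
        label, n_votes = predict_vote(model, block)
        out.append({"sample_id": sid, "predicted": label, "n_votes_for_winner": n_votes})
    return pd.DataFrame(out).set_index("sample_id")


@dataclass
class EvaluationReport:
    classes: list
    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class_recall: np.ndarray

    def metrics(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def evaluate(y_true, y_pred, classes: list | None = None) -> EvaluationReport:
    """Accuracy and macro metrics from the confusion matrix.

    Per-class precision with zero predicted positives is counted as 0
    (logged); macro-F1 is 2PR/(P+R) on the macro averages.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label lists differ in length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    tp = np.diag(cm).astype(float)
    pred_pos = cm.sum(axis=0).astype(float)
    actual = cm.sum(axis=1).astype(float)
    accuracy = tp.sum() / cm.sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        recall = np.where(actual > 0, tp / actual, 0.0)
    if (pred_pos == 0).any():
        logger.warning("classes never predicted: %s",
                       [c for c, n in zip(classes, pred_pos) if n == 0])
    macro_p = float(precision.mean())
    macro_r = float(recall.mean())
    macro_f1 = 2 * macro_p * macro_r / (macro_p + macro_r) if macro_p + macro_r else 0.0
    return EvaluationReport(
        classes=list(classes), confusion=cm, accuracy=float(accuracy),
        macro_precision=macro_p, macro_recall=macro_r, macro_f1=float(macro_f1),
        per_class_recall=recall,
    )


def mean_report(reports: list[EvaluationReport]) -> dict:
    """Arithmetic mean of fold metrics."""
    keys = ["accuracy", "macro_precision", "macro_recall", "macro_f1"]
    return {k: float(np.mean([r.metrics()[k] for r in reports])) for k in keys}


def cross_validate(
    ds,
    edge_sets: dict,
    k: int = 10,
    P: int | None = None,
    n_sets: int = 10,
    cfg: ClassifierConfig | None = None,
    balance_to: int | None = None,
    seed: int = 0,
) -> tuple[list[EvaluationReport], dict]:
    """Stratified k-fold CV; reference sets and model rebuilt per fold.

    Returns the per-fold reports and their metric means. Specific edges
    are taken as given; each fold's reference networks use only that
    fold's training samples.
    """
    from . import features as feat  # local import to avoid cycles

    sizes = ds.labels.value_counts()
    if k < 2:
        raise ValueError("k must be >= 2")
    if (sizes < k).any():
        raise ValueError("every subtype must have at least k samples")
    ids = np.array(ds.sample_ids)
    y = ds.labels.loc[ids].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, te) in enumerate(skf.split(ids, y)):
        train_ids, test_ids = sorted(ids[tr]), sorted(ids[te])
        refs = feat.build_reference_sets(
            ds, train_ids, edge_sets, P=P, n_sets=n_sets, seed=seed + fold
        )
        feat.audit_no_leak(refs, test_ids)
        train_df = feat.featurize_training(
            ds, train_ids, refs, edge_sets, balance_to=balance_to, seed=seed + fold
        )
        model = train(train_df, cfg)
        test_df = feat.featurize_samples(ds, test_ids, refs, edge_sets)
        preds = predict_samples(model, test_df)
        y_true = [ds.labels[s] for s in preds.index]
        reports.append(evaluate(y_true, preds["predicted"], classes=ds.subtypes))
    return reports, mean_report(reports)
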