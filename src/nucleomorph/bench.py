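"""Seven fixed classifier configurations with confusion-matrix metrics,
ROC curves and AUC.

The classifier zoo mirrors a common benchmarking setup for tabular
morphometric features:

* ``nn64`` — one hidden layer of 64 ReLU units, sigmoid output trained with
  binary cross-entropy and Adam (realised as an MLP; 200 epochs, batch 32,
  learning rate 1e-3, no early stopping);
* ``mlp``  — one hidden layer of 100 units, ReLU, max 500 iterations;
* ``rf``   — random forest, 100 trees;
* ``tree`` — decision tree capped at 100 internal splits, Gini impurity;
* ``svm_linear`` — linear-kernel SVM, box constraint C=1, standardized inputs;
* ``knn1`` — 1-nearest-neighbour, Euclidean, equal weights, standardized inputs;
* ``nnn10`` — narrow network: one fully connected layer of 10 ReLU units,
  iteration limit 1000, regularisation strength 0.

Inputs are standardized for the SVM and KNN, min-max scaled to [0, 1] for
the three neural models, and left raw for the tree ensembles. Scaling
statistics are always fitted on the training partition only.

Evaluation uses a stratified 80/20 split shared by all classifiers,
accuracy and macro-averaged precision/recall/F1 from the confusion counts,
and an in-package threshold-sweep ROC with trapezoidal AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierConfig",
    "ConfusionCounts",
    "EvaluationReport",
    "make_classifier",
    "split_dataset",
    "train_classifier",
    "compute_metrics",
    "roc_curve",
    "evaluate_classifier",
    "run_bench",
]

CLASSIFIER_NAMES = ("nn64", "mlp", "rf", "tree", "svm_linear", "knn1", "nnn10")


@dataclass(frozen=True)
class ClassifierConfig:
    name: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; valid names: {', '.join(CLASSIFIER_NAMES)}"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with 'malignant' as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvaluationReport:
    classifier: str
    counts: ConfusionCounts
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class: dict
    roc: list  # [(FPR, TPR), ...]
    auc: float
    split_seed: int

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "counts": {
                "TP": self.counts.TP,
                "TN": self.counts.TN,
                "FP": self.counts.FP,
                "FN": self.counts.FN,
            },
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "per_class": self.per_class,
            "auc": self.auc,
            "roc": self.roc,
            "split_seed": self.split_seed,
        }


def make_classifier(config: ClassifierConfig) -> Pipeline:
    """Build the scikit-learn pipeline for one named configuration."""
    name, seed = config.name, config.seed
    if name == "nn64":
        est = MLPClassifier(
            hidden_layer_sizes=(64,),
            activation="relu",
            solver="adam",
            learning_rate_init=1e-3,
            batch_size=32,
            max_iter=200,
            early_stopping=False,
            random_state=seed,
        )
        scaler = MinMaxScaler()
    elif name == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=(100,), activation="relu", max_iter=500, random_state=seed
        )
        scaler = MinMaxScaler()
    elif name == "nnn10":
        est = MLPClassifier(
            hidden_layer_sizes=(10,),
            activation="relu",
            max_iter=1000,
            alpha=0.0,
            random_state=seed,
        )
        scaler = MinMaxScaler()
    elif name == "rf":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
        scaler = None
    elif name == "tree":
        # <= 100 internal split nodes == <= 101 leaves in a binary tree
        est = DecisionTreeClassifier(max_leaf_nodes=101, criterion="gini", random_state=seed)
        scaler = None
    elif name == "svm_linear":
        est = SVC(kernel="linear", C=1.0, random_state=seed)
        scaler = StandardScaler()
    elif name == "knn1":
        est = KNeighborsClassifier(n_neighbors=1, metric="euclidean", weights="uniform")
        scaler = StandardScaler()
    steps = ([("scale", scaler)] if scaler is not None else []) + [("clf", est)]
    return Pipeline(steps)


def split_dataset(features: np.ndarray, labels: np.ndarray, train_fraction: float = 0.8, seed: int = 0):
    """Stratified shuffle split into (X_train, X_test, y_train, y_test)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need >= 2 samples in each of two classes")
    return train_test_split(
        np.asarray(features),
        y,
        train_size=train_fraction,
        stratify=y,
        random_state=seed,
        shuffle=True,
    )


def _check_finite(X: np.ndarray) -> None:
    X = np.asarray(X, dtype=float)
    bad = ~np.isfinite(X)
    if bad.any():
        cols = sorted(set(np.nonzero(bad)[1].tolist()))
        raise ValueError(f"non-finite feature values in column(s) {cols}")


def train_classifier(config: ClassifierConfig, X_train: np.ndarray, y_train: np.ndarray) -> Pipeline:
    """Fit one configuration; raises on non-finite features, naming the column."""
    _check_finite(X_train)
    model = make_classifier(config)
    model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
    return model


def decision_scores(model: Pipeline, X: np.ndarray, positive_label) -> np.ndarray:
    """Continuous score for the positive class (probability or margin)."""
    if hasattr(model, "predict_proba"):
        try:
            proba = model.predict_proba(X)
            pos = list(model.classes_).index(positive_label)
            return proba[:, pos]
        except AttributeError:
            pass
    scores = model.decision_function(X)
    if list(model.classes_).index(positive_label) == 0:
        scores = -scores
    return scores


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy and per-class + macro precision/recall/F1 from the counts.

    Each class is treated in turn as positive; macro values are the
    unweighted mean of the two per-class values. A zero denominator (no
    predicted positives / no true positives) defines that ratio as 0.
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")

    def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        )
        return precision, recall, f1

    p_pos, r_pos, f_pos = prf(counts.TP, counts.FP, counts.FN)
    p_neg, r_neg, f_neg = prf(counts.TN, counts.FN, counts.FP)
    return {
        "accuracy": (counts.TN + counts.TP) / counts.total,
        "per_class": {
            "positive": {"precision": p_pos, "recall": r_pos, "f1": f_pos},
            "negative": {"precision": p_neg, "recall": r_neg, "f1": f_neg},
        },
        "precision_macro": (p_pos + p_neg) / 2,
        "recall_macro": (r_pos + r_neg) / 2,
        "f1_macro": (f_pos + f_neg) / 2,
    }


def roc_curve(scores: np.ndarray, labels: np.ndarray, positive_label=1):
    """Threshold-sweep ROC curve and trapezoidal AUC.

    Thresholds sweep the unique scores in descending order; the returned
    points start at (0, 0) and end at (1, 1) and are monotone non-decreasing
    in both coordinates. Tied positive/negative scores contribute the
    half-credit diagonal segment, so the trapezoidal area equals the
    Mann-Whitney pair-counting statistic exactly.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel() == positive_label
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    yy = y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[j] == s[i]:  # process a tie block at once
            tp += int(yy[j])
            fp += int(not yy[j])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return [tuple(p) for p in pts], auc


def evaluate_classifier(
    config: ClassifierConfig,
    X_train,
    X_test,
    y_train,
    y_test,
    positive_label="malignant",
    split_seed: int = 0,
) -> EvaluationReport:
    """Train one configuration and evaluate it on the held-out split."""
    model = train_classifier(config, X_train, y_train)
    _check_finite(X_test)
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    pred = model.predict(X_test)
    pos = y_test == positive_label
    hit = pred == y_test
    counts = ConfusionCounts(
        TP=int(np.sum(pos & hit)),
        TN=int(np.sum(~pos & hit)),
        FP=int(np.sum(~pos & ~hit)),
        FN=int(np.sum(pos & ~hit)),
    )
    metrics = compute_metrics(counts)
    scores = decision_scores(model, X_test, positive_label)
    roc, auc = roc_curve(scores, y_test, positive_label)
    return EvaluationReport(
        classifier=config.name,
        counts=counts,
        accuracy=metrics["accuracy"],
        precision_macro=metrics["precision_macro"],
        recall_macro=metrics["recall_macro"],
        f1_macro=metrics["f1_macro"],
        per_class=metrics["per_class"],
        roc=roc,
        auc=auc,
        split_seed=split_seed,
    )


def run_bench(
    features: pd.DataFrame,
    classifiers: list[str] | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    positive_label: str = "malignant",
) -> dict[str, EvaluationReport]:
    """Benchmark the classifier zoo on a feature table.

    ``features`` needs numeric feature columns plus a ``label`` column; one
    stratified 80/20 split (from ``seed``) is shared by all classifiers.
    When ``outdir`` is given, writes ``summary.csv`` (classifier x metrics),
    per-classifier JSON reports and ROC point CSVs.
    """
    classifiers = list(classifiers) if classifiers else list(CLASSIFIER_NAMES)
    for name in classifiers:
        ClassifierConfig(name)  # validates early
    if "label" not in features.columns:
        raise ValueError("feature table must contain a 'label' column")
    feat_cols = [c for c in features.columns if c not in ("label", "image")]
    X = features[feat_cols].to_numpy(dtype=float)
    y = features["label"].to_numpy()
    X_train, X_test, y_train, y_test = split_dataset(X, y, 0.8, seed)

    reports: dict[str, EvaluationReport] = {}
    for name in classifiers:
        reports[name] = evaluate_classifier(
            ClassifierConfig(name, seed=seed),
            X_train,
            X_test,
            y_train,
            y_test,
            positive_label=positive_label,
            split_seed=seed,
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for name, rep in reports.items():
            rows.append(
                {
                    "classifier": name,
                    "accuracy": rep.accuracy,
                    "precision_macro": rep.precision_macro,
                    "recall_macro": rep.recall_macro,
                    "f1_macro": rep.f1_macro,
                    "auc": rep.auc,
                }
            )
            (outdir / f"{name}.json").write_text(json.dumps(rep.to_dict(), indent=2) + "\n")
            pd.DataFrame(rep.roc, columns=["fpr", "tpr"]).to_csv(
                outdir / f"{name}_roc.csv", index=False
            )
        pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False)
    return reports
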