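"""Classifier training and repeated-split evaluation.

Four binary classifiers are compared: L2 logistic regression, a linear
soft-margin SVM (C = 1), linear discriminant analysis, and a fully
connected neural network with one hidden layer of 32 ReLU units trained
full-batch with L-BFGS (at most 200 iterations).

The default protocol repeats 100 times: stratified 85/15 train/test split,
z-scoring and PCA (k = 11) fitted on the training rows only, all four
classifiers fitted, and accuracy (%), precision, recall and ROC AUC
measured on the held-out rows.  The report carries the mean and standard
deviation of each metric over the repeats.  A stratified k-fold variant is
available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .selection import SelectionResult, pca_fit_transform

__all__ = [
    "CLASSIFIERS",
    "EvalProtocol",
    "ClassificationReport",
    "fit_predict",
    "metrics",
    "evaluate",
]

CLASSIFIERS = ("logistic", "svm_linear", "lda", "ann")


def _make_model(method: str, seed: int):
    if method == "logistic":
        return LogisticRegression(C=1.0, max_iter=1000)
    if method == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    if method == "lda":
        return LinearDiscriminantAnalysis()
    if method == "ann":
        return MLPClassifier(
            hidden_layer_sizes=(32,),
            activation="relu",
            solver="lbfgs",
            max_iter=200,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier {method!r}")


def fit_predict(
    method: str,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one classifier; return predicted labels and continuous scores.

    Scores are decision-function margins or positive-class probabilities,
    suitable for ROC AUC.
    """
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training labels contain a single class")
    model = _make_model(method, seed)
    model.fit(train_X, train_y)
    labels = model.predict(test_X)
    if hasattr(model, "decision_function"):
        scores = model.decision_function(test_X)
    else:
        scores = model.predict_proba(test_X)[:, list(model.classes_).index(1)]
    return labels, scores


def metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
) -> dict:
    """Binary accuracy (%), precision, recall and ROC AUC (positive class = 1).

    Precision with no positive predictions is reported as 0 (flagged in the
    returned dict).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("empty or misaligned label vectors")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    no_positive_predictions = (tp + fp) == 0
    precision = 0.0 if no_positive_predictions else tp / (tp + fp)
    recall = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    accuracy = 100.0 * float(np.mean(y_true == y_pred))
    auc = float(roc_auc_score(y_true, scores)) if len(np.unique(y_true)) == 2 else np.nan
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "auc": auc,
        "undefined_precision": no_positive_predictions,
    }


@dataclass
class EvalProtocol:
    """Repeated-split (or k-fold) evaluation settings."""

    n_repeats: int = 100
    test_fraction: float = 0.15
    pca_k: int = 11
    seed: int = 0
    mode: str = "repeated_split"  # or "kfold"
    n_folds: int = 5

    def validate(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        if self.mode not in ("repeated_split", "kfold"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ClassificationReport:
    """Mean +/- SD of each metric per classifier over evaluation repeats."""

    stats: dict  # classifier -> metric -> (mean, sd)
    n_repeats: int
    positive_group: str
    groups: tuple
    per_repeat: dict = field(default_factory=dict, repr=False)

    def mean(self, classifier: str, metric: str) -> float:
        return self.stats[classifier][metric][0]

    def sd(self, classifier: str, metric: str) -> float:
        return self.stats[classifier][metric][1]

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "positive_group": self.positive_group,
            "n_repeats": self.n_repeats,
            "stats": {
                clf: {m: {"mean": v[0], "sd": v[1]} for m, v in d.items()}
                for clf, d in self.stats.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def render_table(self) -> str:
        """Plain-text table: one classifier per row, mean +/- SD per metric."""
        names = {
            "logistic": "Logistic Regression",
            "svm_linear": "SVM",
            "lda": "LDA",
            "ann": "ANN",
        }
        head = f"{'Classifier':<22}{'Accuracy (%)':<18}{'Precision':<16}{'Recall':<16}{'AUC':<16}"
        lines = [f"{self.groups[0]} vs {self.groups[1]}", head, "-" * len(head)]
        for clf in CLASSIFIERS:
            if clf not in self.stats:
                continue
            row = f"{names.get(clf, clf):<22}"
            acc_m, acc_s = self.stats[clf]["accuracy"]
            row += f"{acc_m:6.2f} ± {acc_s:<6.2f}   "
            for m in ("precision", "recall", "auc"):
                mu, sd = self.stats[clf][m]
                row += f"{mu:4.2f} ± {sd:<4.2f}     "
            lines.append(row)
        return "\n".join(lines) + "\n"


def _split_indices(y, test_fraction, rng_seed):
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=rng_seed
    )
    return train, test


def evaluate(
    features: pd.DataFrame,
    selection: SelectionResult,
    protocol: EvalProtocol,
    eval_pair: tuple | None = None,
    positive_group: str | None = None,
    classifiers: tuple = CLASSIFIERS,
) -> ClassificationReport:
    """Repeated-split evaluation of the selected feature columns.

    ``features`` is a cohort feature matrix with a ``group`` column; the
    rows evaluated are those of ``eval_pair`` (default: the pair the
    screening was computed on, enabling the generalisation path where a
    mask from one comparison is applied to another group pair).  The
    positive class defaults to the first group of the pair (the patient
    group by convention).

    Per repeat: stratified split, PCA (fitted on training rows only,
    ``k = min(pca_k, columns, n_train - 1)``), all classifiers fitted and
    scored on the held-out rows.
    """
    protocol.validate()
    pair = tuple(eval_pair) if eval_pair is not None else tuple(selection.group_pair)
    cols = selection.selected_columns
    if not cols:
        raise ValueError("no selected feature columns to evaluate")
    sub = features[features["group"].isin(pair)]
    if sub["group"].nunique() < 2:
        raise ValueError(f"need subjects from both groups {pair}")
    positive = positive_group if positive_group is not None else pair[0]
    X = sub[cols].to_numpy(dtype=float)
    y = (sub["group"] == positive).to_numpy(dtype=int)
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("each class needs at least two subjects")

    if protocol.mode == "kfold":
        splitter = StratifiedKFold(
            n_splits=protocol.n_folds, shuffle=True, random_state=protocol.seed
        )
        splits = list(splitter.split(X, y))
    else:
        splits = [
            _split_indices(y, protocol.test_fraction, (protocol.seed * 1009 + r) % (2**31))
            for r in range(protocol.n_repeats)
        ]

    per_repeat = {clf: [] for clf in classifiers}
    for r, (tr, te) in enumerate(splits):
        n_informative = int(np.count_nonzero(X[tr].var(axis=0) > 0))
        if n_informative == 0:
            raise ValueError("all selected columns are constant on a training split")
        k = min(protocol.pca_k, n_informative, len(tr) - 1)
        Ztr, Zte, _ = pca_fit_transform(X[tr], X[te], k=k, scale=True)
        rep_seed = (protocol.seed * 1009 + 7 * r + 1) % (2**31)
        for clf in classifiers:
            labels, scores = fit_predict(clf, Ztr, y[tr], Zte, seed=rep_seed)
            per_repeat[clf].append(metrics(y[te], labels, scores))

    stats = {}
    for clf in classifiers:
        stats[clf] = {}
        for m in ("accuracy", "precision", "recall", "auc"):
            vals = np.array([row[m] for row in per_repeat[clf]], dtype=float)
            sd = float(vals.std(ddof=0)) if len(vals) > 1 else 0.0
            stats[clf][m] = (float(vals.mean()), sd)

    return ClassificationReport(
        stats=stats,
        n_repeats=len(splits),
        positive_group=positive,
        groups=pair,
        per_repeat=per_repeat,
    )
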