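"""Evaluation of patient representations.

Two complementary views: (1) disease status prediction with a feed-forward
classifier under stratified k-fold cross-validation — auxiliary cohorts join
every fold's training pool in full but never the held-out split — reporting
precision, recall, F1 of the case class and the support-weighted average F1;
(2) label-based clustering quality over the original representation vectors
(Calinski-Harabasz, Davies-Bouldin, silhouette) plus an optional 2-D
projection for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import (
    accuracy_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    f1_score,
    precision_score,
    recall_score,
    silhouette_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

__all__ = [
    "FoldAssignment",
    "EvaluationReport",
    "stratified_kfold",
    "evaluate_classification",
    "clustering_scores",
    "project_2d",
]


@dataclass(frozen=True)
class FoldAssignment:
    """A stratified partition of one cohort into k folds."""

    k: int
    fold_of: Mapping[str, int]

    def test_ids(self, fold: int) -> list[str]:
        return [p for p, f in self.fold_of.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [p for p, f in self.fold_of.items() if f != fold]


@dataclass
class EvaluationReport:
    """Per-fold and aggregate metrics for one strategy x method combination."""

    strategy: str
    method: str
    per_fold: list[dict[str, float]] = field(default_factory=list)
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    clustering: dict[str, float] = field(default_factory=dict)

    def aggregate(self) -> None:
        keys = self.per_fold[0].keys() if self.per_fold else ()
        for key in keys:
            vals = np.array([f[key] for f in self.per_fold])
            self.mean[key] = float(vals.mean())
            self.sd[key] = float(vals.std())

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "method": self.method,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
            "clustering": self.clustering,
        }


def stratified_kfold(
    labels: Mapping[str, str], k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Partition patients into k folds preserving class proportions.

    Per-fold class counts differ from perfect proportionality by less than
    one. Deterministic under the seed, so the same folds can be reused across
    every strategy and method. A class with fewer than k members is an error.
    """
    patients = sorted(labels)
    y = [labels[p] for p in patients]
    for cls in set(y):
        if y.count(cls) < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            fold_of[patients[i]] = fold
    return FoldAssignment(k=k, fold_of=fold_of)


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "weighted_f1": float(
            f1_score(y_true, y_pred, average="weighted", zero_division=0)
        ),
    }


def evaluate_classification(
    primary_vectors: np.ndarray,
    primary_ids: Sequence[str],
    primary_labels: Mapping[str, str],
    folds: FoldAssignment,
    aux_vectors: Optional[np.ndarray] = None,
    aux_labels: Optional[Sequence[str]] = None,
    strategy: str = "",
    method: str = "",
    seed: int = 0,
    hidden: int = 100,
    max_iter: int = 500,
) -> EvaluationReport:
    """Cross-validated classification of the primary cohort.

    Per fold, a one-hidden-layer feed-forward network (width ``hidden``,
    rectifier activation, adaptive-moment optimizer, fixed seed) is fit on
    the primary training split pooled with all auxiliary patients, then
    scored on the held-out split. Raises on label leakage (a test patient in
    the training pool).
    """
    pos = {p: i for i, p in enumerate(primary_ids)}
    unknown = set(folds.fold_of) - set(pos)
    if unknown:
        raise ValueError(f"fold patients missing from matrix: {sorted(unknown)[:5]}")
    y_of = {p: 1 if primary_labels[p] == "case" else 0 for p in folds.fold_of}
    if aux_vectors is not None:
        if aux_labels is None or len(aux_labels) != len(aux_vectors):
            raise ValueError("aux_labels must align with aux_vectors")
        y_aux = np.array(
            [1 if l == "case" else 0 for l in aux_labels], dtype=int
        )
    report = EvaluationReport(strategy=strategy, method=method)
    for fold in range(folds.k):
        train_ids = folds.train_ids(fold)
        test_ids = folds.test_ids(fold)
        if set(train_ids) & set(test_ids):
            raise ValueError(f"label leakage in fold {fold}")
        X_train = primary_vectors[[pos[p] for p in train_ids]]
        y_train = np.array([y_of[p] for p in train_ids], dtype=int)
        if aux_vectors is not None and len(aux_vectors):
            X_train = np.vstack([X_train, aux_vectors])
            y_train = np.concatenate([y_train, y_aux])
        X_test = primary_vectors[[pos[p] for p in test_ids]]
        y_test = np.array([y_of[p] for p in test_ids], dtype=int)
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            activation="relu",
            solver="adam",
            max_iter=max_iter,
            random_state=seed,
        )
        clf.fit(X_train, y_train)
        report.per_fold.append(_fold_metrics(y_test, clf.predict(X_test)))
    report.aggregate()
    return report


def clustering_scores(
    matrix: np.ndarray, labels: Sequence
) -> tuple[float, float, float]:
    """(Calinski-Harabasz, Davies-Bouldin, silhouette) of the labelled points.

    Computed over the original representation vectors with Euclidean
    distance. Requires at least two distinct labels, each with two or more
    members (silhouette is undefined otherwise).
    """
    labels = np.asarray(labels)
    matrix = np.asarray(matrix, dtype=float)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("clustering scores undefined for a single cluster")
    if counts.min() < 2:
        raise ValueError("each cluster needs at least two points for silhouette")
    ch = float(calinski_harabasz_score(matrix, labels))
    db = float(davies_bouldin_score(matrix, labels))
    sil = float(silhouette_score(matrix, labels, metric="euclidean"))
    return ch, db, sil


def project_2d(
    matrix: np.ndarray,
    seed: int = 0,
    labels: Optional[Sequence] = None,
    origins: Optional[Sequence[str]] = None,
    perplexity: Optional[float] = None,
) -> dict:
    """t-SNE projection to 2-D for visual inspection of the embedding space.

    Returns coordinates plus the pass-through labels and dataset-of-origin
    tags so callers can color the scatter plot. Not part of any quantitative
    comparison.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("need at least three points for a 2-D projection")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(matrix)
    out = {"coords": coords}
    if labels is not None:
        if len(labels) != n:
            raise ValueError("labels length mismatch")
        out["labels"] = list(labels)
    if origins is not None:
        if len(origins) != n:
            raise ValueError("origins length mismatch")
        out["origins"] = list(origins)
    return out
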