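"""Trainable CPC predictors over the shared count-feature space.

Four families:

- ``KnnCpcClassifier`` — similarity-weighted vote of the 10 nearest labeled
  referrals, with Euclidean distance converted to similarity via exp(-d);
  only neighbours with similarity > 0 may vote.
- ``SupervisedCpcClassifier`` — an opaque trainable multiclass classifier
  (any standard implementation) optionally wrapped in a one-vs-rest,
  one-vs-one or error-correcting output-code strategy.
- ``SelfTrainingCpcClassifier`` — self-training: iteratively pseudo-labels
  unlabeled referrals whose top-class confidence reaches 0.75 and retrains
  until no additions or the iteration cap.
- ``SeededKMeansCpc`` — Lloyd's k-means with one cluster per CPC, centroids
  initialized from CPC seed texts so each cluster is pre-bound to a CPC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import euclidean_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import (
    OneVsOneClassifier,
    OneVsRestClassifier,
    OutputCodeClassifier,
)
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

NO_PREDICTION = "__no_prediction__"  # sentinel: no neighbour with similarity > 0

DEFAULT_K = 10
DEFAULT_PSEUDO_LABEL_THRESHOLD = 0.75
DEFAULT_SELF_TRAIN_MAX_ITER = 10
DEFAULT_KMEANS_MAX_ITER = 300
DEFAULT_KMEANS_TOL = 1e-4


def _as_dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)


# ---------------------------------------------------------------------------
# KNN


def euc_similarity(a, b) -> float:
    """exp(-Euclidean distance): 1 at distance 0, strictly decreasing."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return math.exp(-float(np.linalg.norm(a - b)))


def knn_predict(
    vector,
    labeled: Sequence[tuple[Sequence[float], str]],
    k: int = DEFAULT_K,
) -> tuple[str, dict[str, float]]:
    """Similarity-weighted CPC vote of the top-k nearest labeled referrals.

    Returns (cpc_id, vote map); cpc_id is NO_PREDICTION when no neighbour has
    similarity > 0. Ties break toward the ascending cpc_id.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not labeled:
        raise ValueError("labeled set must be non-empty")
    vec = np.asarray(vector, dtype=float).ravel()
    sims = np.array(
        [euc_similarity(vec, np.asarray(v, dtype=float).ravel()) for v, _ in labeled]
    )
    order = np.argsort(-sims, kind="stable")[:k]
    votes: dict[str, float] = {}
    for idx in order:
        if sims[idx] > 0.0:
            cid = labeled[idx][1]
            votes[cid] = votes.get(cid, 0.0) + float(sims[idx])
    if not votes:
        return NO_PREDICTION, {}
    best = max(votes.values())
    return min(c for c, w in votes.items() if w == best), votes


class KnnCpcClassifier(BaseEstimator, ClassifierMixin):
    """K-nearest-neighbour CPC classifier with exp(-distance) vote weights."""

    def __init__(self, k: int = DEFAULT_K):
        self.k = k

    def fit(self, X, y):
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        self.X_ = _as_dense(X)
        self.y_ = np.asarray(y, dtype=object)
        if len(self.y_) == 0:
            raise ValueError("labeled set must be non-empty")
        self.classes_ = np.unique(self.y_)
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_dense(X)
        dists = euclidean_distances(X, self.X_)
        sims = np.exp(-dists)
        out = []
        for row in sims:
            order = np.argsort(-row, kind="stable")[: self.k]
            votes: dict[str, float] = {}
            for idx in order:
                if row[idx] > 0.0:
                    cid = self.y_[idx]
                    votes[cid] = votes.get(cid, 0.0) + float(row[idx])
            if not votes:
                out.append(NO_PREDICTION)
            else:
                best = max(votes.values())
                out.append(min(c for c, w in votes.items() if w == best))
        return np.asarray(out, dtype=object)


# ---------------------------------------------------------------------------
# Supervised


@dataclass
class ClassifierSpec:
    """Opaque trainable-classifier contract: an algorithm name, a multiclass
    strategy, and a hyperparameter map passed through verbatim."""

    algorithm: str = "logistic_regression"
    multiclass_strategy: str = "native"  # native | ovr | ovo | error_correcting
    hyperparameters: dict = field(default_factory=dict)


_ALGORITHMS = {
    "logistic_regression": (LogisticRegression, {"max_iter": 1000}),
    "linear_svm": (LinearSVC, {}),
    "sgd": (SGDClassifier, {}),
    "sgd_perceptron": (SGDClassifier, {"loss": "perceptron"}),
    "random_forest": (RandomForestClassifier, {}),
    "gradient_boosting": (GradientBoostingClassifier, {}),
    "mlp": (MLPClassifier, {"max_iter": 500}),
}


def _base_estimator(spec: ClassifierSpec, seed: int):
    try:
        cls, defaults = _ALGORITHMS[spec.algorithm]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {spec.algorithm!r}; one of {sorted(_ALGORITHMS)}"
        ) from None
    params = {**defaults, **spec.hyperparameters}
    if "random_state" in cls().get_params():
        params.setdefault("random_state", seed)
    return cls(**params)


class SupervisedCpcClassifier(BaseEstimator, ClassifierMixin):
    """Multiclass CPC classifier behind the opaque-classifier contract.

    ``predict_confidence`` always returns per-class scores in [0, 1] summing
    to 1 per row: predict_proba when the underlying model provides it, else a
    softmax over its decision function.
    """

    def __init__(self, spec: ClassifierSpec | None = None, seed: int = 0):
        self.spec = spec
        self.seed = seed

    def fit(self, X, y):
        spec = self.spec or ClassifierSpec()
        y = np.asarray(y, dtype=object)
        if len(np.unique(y)) < 2:
            raise ValueError("supervised training requires >= 2 distinct CPC labels")
        base = _base_estimator(spec, self.seed)
        strategy = spec.multiclass_strategy
        if strategy == "native":
            model = base
        elif strategy == "ovr":
            model = OneVsRestClassifier(base)
        elif strategy == "ovo":
            model = OneVsOneClassifier(base)
        elif strategy == "error_correcting":
            model = OutputCodeClassifier(base, random_state=self.seed)
        else:
            raise ValueError(f"unknown multiclass strategy {strategy!r}")
        self.model_ = model.fit(X, y)
        self.classes_ = np.asarray(self.model_.classes_, dtype=object)
        return self

    @property
    def n_binary_problems_(self) -> int:
        """Number of underlying binary classifiers for wrapped strategies."""
        if hasattr(self.model_, "estimators_"):
            return len(self.model_.estimators_)
        return 1

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.model_.predict(X), dtype=object)

    def predict_confidence(self, X) -> np.ndarray:
        if hasattr(self.model_, "predict_proba"):
            proba = np.asarray(self.model_.predict_proba(X), dtype=float)
        else:
            scores = np.asarray(self.model_.decision_function(X), dtype=float)
            if scores.ndim == 1:  # binary: expand to two columns
                scores = np.column_stack([-scores, scores])
            proba = softmax(scores, axis=1)
        return proba


def train_supervised(
    features, labels, spec: ClassifierSpec | None = None, seed: int = 0
) -> SupervisedCpcClassifier:
    return SupervisedCpcClassifier(spec=spec, seed=seed).fit(features, labels)


def stratified_cv(
    features,
    labels,
    spec: ClassifierSpec | None = None,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation: every row is tested exactly once;
    per-class fold counts differ by at most one.

    Returns fold test indices/sizes, per-fold accuracies and the pooled
    accuracy (total correct / n).
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"cannot split {n} rows into {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_indices, fold_acc, correct_total = [], [], 0
    X = features
    for train_idx, test_idx in skf.split(np.zeros(n), labels):
        fold_indices.append(test_idx)
        model = SupervisedCpcClassifier(spec=spec, seed=seed).fit(
            X[train_idx], labels[train_idx]
        )
        pred = model.predict(X[test_idx])
        n_correct = int(np.sum(pred == labels[test_idx]))
        correct_total += n_correct
        fold_acc.append(n_correct / len(test_idx))
    return {
        "fold_test_indices": fold_indices,
        "fold_test_sizes": [len(ix) for ix in fold_indices],
        "fold_accuracies": fold_acc,
        "pooled_accuracy": correct_total / n,
    }


def stratified_fold_sizes(n: int, folds: int = 5) -> list[int]:
    """Test-fold sizes of an n-row stratified k-fold split (descending)."""
    base, extra = divmod(n, folds)
    return [base + 1] * extra + [base] * (folds - extra)


# ---------------------------------------------------------------------------
# Self-training


@dataclass
class PseudoLabel:
    iteration: int
    row: int
    label: str
    confidence: float


class SelfTrainingCpcClassifier(BaseEstimator, ClassifierMixin):
    """Self-training semi-supervised CPC classifier.

    Each iteration trains the base supervised model on the current labeled
    pool, then moves every unlabeled row whose top-class confidence is at
    least ``threshold`` (default 0.75, deliberately above the plain 0.5
    decision threshold) into the pool under its pseudo-label. Stops when an
    iteration adds nothing or after ``max_iter`` iterations.
    """

    def __init__(
        self,
        spec: ClassifierSpec | None = None,
        threshold: float = DEFAULT_PSEUDO_LABEL_THRESHOLD,
        max_iter: int = DEFAULT_SELF_TRAIN_MAX_ITER,
        seed: int = 0,
    ):
        self.spec = spec
        self.threshold = threshold
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y, X_unlabeled=None):
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError(
                f"pseudo-label threshold must be in (0.5, 1], got {self.threshold}"
            )
        X = _as_dense(X)
        y = np.asarray(y, dtype=object)
        pool_X, pool_y = X, y
        log: list[PseudoLabel] = []
        model = SupervisedCpcClassifier(spec=self.spec, seed=self.seed)
        if X_unlabeled is None or len(_as_dense(X_unlabeled)) == 0:
            model.fit(pool_X, pool_y)
            self.model_, self.pseudo_labels_, self.n_iterations_ = model, log, 0
            self.classes_ = model.classes_
            return self
        U = _as_dense(X_unlabeled)
        remaining = np.arange(len(U))
        iteration = 0
        while iteration < self.max_iter:
            iteration += 1
            model = SupervisedCpcClassifier(spec=self.spec, seed=self.seed)
            model.fit(pool_X, pool_y)
            if len(remaining) == 0:
                break
            conf = model.predict_confidence(U[remaining])
            top = conf.max(axis=1)
            take = top >= self.threshold
            if not take.any():
                break
            labels = model.classes_[conf.argmax(axis=1)]
            for row, lab, c in zip(remaining[take], labels[take], top[take]):
                log.append(PseudoLabel(iteration, int(row), str(lab), float(c)))
            pool_X = np.vstack([pool_X, U[remaining[take]]])
            pool_y = np.concatenate([pool_y, labels[take]])
            remaining = remaining[~take]
        # final refit on the grown pool
        self.model_ = SupervisedCpcClassifier(spec=self.spec, seed=self.seed).fit(
            pool_X, pool_y
        )
        self.pseudo_labels_ = log
        self.n_iterations_ = iteration
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(_as_dense(X))

    def predict_confidence(self, X) -> np.ndarray:
        return self.model_.predict_confidence(_as_dense(X))


def self_train(
    labeled_X,
    labeled_y,
    unlabeled_X,
    spec: ClassifierSpec | None = None,
    threshold: float = DEFAULT_PSEUDO_LABEL_THRESHOLD,
    max_iter: int = DEFAULT_SELF_TRAIN_MAX_ITER,
    seed: int = 0,
) -> tuple[SelfTrainingCpcClassifier, list[PseudoLabel]]:
    model = SelfTrainingCpcClassifier(spec, threshold, max_iter, seed)
    model.fit(labeled_X, labeled_y, unlabeled_X)
    return model, model.pseudo_labels_


# ---------------------------------------------------------------------------
# Seeded k-means


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    seed_labels: list[str]
    objective_trace: list[float]
    n_iterations: int


class SeededKMeansCpc(BaseEstimator, ClassifierMixin):
    """Lloyd's k-means with one cluster per CPC.

    Centroids start at the vectorized CPC seed texts, so every cluster is
    bound to a CPC from the outset and cluster assignment doubles as CPC
    prediction. Clusters that empty keep their previous centroid (frozen), so
    k never degenerates. The within-cluster sum of squares is recorded per
    iteration and is non-increasing.
    """

    def __init__(
        self,
        seeds: dict[str, Sequence[float]] | None = None,
        max_iter: int = DEFAULT_KMEANS_MAX_ITER,
        tol: float = DEFAULT_KMEANS_TOL,
    ):
        self.seeds = seeds
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        if not self.seeds or len(self.seeds) < 2:
            raise ValueError("seeded k-means needs >= 2 seed vectors")
        labels = sorted(self.seeds)  # ascending cpc_id: argmin ties -> low id
        cents = np.array(
            [np.asarray(self.seeds[c], dtype=float).ravel() for c in labels]
        )
        X = _as_dense(X)
        trace: list[float] = []
        assign = None
        it = 0
        while it < self.max_iter:
            it += 1
            d2 = euclidean_distances(X, cents, squared=True)
            assign = d2.argmin(axis=1)
            trace.append(float(d2[np.arange(len(X)), assign].sum()))
            new_cents = cents.copy()  # empty cluster -> centroid frozen
            for j in range(len(labels)):
                members = assign == j
                if members.any():
                    new_cents[j] = X[members].mean(axis=0)
            move = float(np.abs(new_cents - cents).max())
            cents = new_cents
            if move < self.tol:
                break
        self.classes_ = np.asarray(labels, dtype=object)
        self.cluster_model_ = ClusterModel(
            k=len(labels),
            centroids=cents,
            seed_labels=labels,
            objective_trace=trace,
            n_iterations=it,
        )
        self.labels_ = self.classes_[assign] if assign is not None else None
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_dense(X)
        d2 = euclidean_distances(X, self.cluster_model_.centroids, squared=True)
        return self.classes_[d2.argmin(axis=1)]


def pseudo_labels_to_frame(log: Sequence[PseudoLabel]):
    """Pseudo-label log as a DataFrame (iteration, row, label, confidence),
    ready for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"iteration": p.iteration, "row": p.row, "label": p.label,
             "confidence": p.confidence}
            for p in log
        ],
        columns=["iteration", "row", "label", "confidence"],
    )


def save_model(model, path, vocabulary: Sequence[str] | None = None) -> None:
    """Persist a trained predictor with its configuration, seed and a hash
    of the vocabulary it was trained in (refusing to score a model in the
    wrong feature space is the caller's job, the hash makes it checkable)."""
    import hashlib

    import joblib

    vocab_hash = (
        hashlib.sha256("\n".join(vocabulary).encode()).hexdigest()
        if vocabulary is not None
        else None
    )
    joblib.dump(
        {
            "model": model,
            "params": model.get_params(deep=False),
            "class": type(model).__name__,
            "vocabulary_sha256": vocab_hash,
        },
        path,
    )


def load_model(path) -> tuple[object, dict]:
    """Load a persisted predictor; returns (model, metadata)."""
    import joblib

    envelope = joblib.load(path)
    model = envelope.pop("model")
    return model, envelope


def vectorize_seeds(
    vectorizer, seed_texts: dict[str, Sequence[str]]
) -> dict[str, np.ndarray]:
    """Embed CPC seed token sequences into a fitted count-feature space.

    A seed that vectorizes to all zeros shares no vocabulary with the feature
    space and cannot anchor a cluster; that is a configuration error and is
    reported with the offending CPC's id.
    """
    out: dict[str, np.ndarray] = {}
    for cpc_id, tokens in seed_texts.items():
        vec = vectorizer.transform([list(tokens)])
        row = np.asarray(vec.todense()).ravel() if sp.issparse(vec) else (
            np.asarray(vec, dtype=float).ravel()
        )
        if not row.any():
            raise ValueError(
                f"seed text for CPC {cpc_id!r} vectorizes to all zeros; it "
                "shares no vocabulary with the feature space"
            )
        out[cpc_id] = row
    return out


def seeded_kmeans(
    features,
    seeds: dict[str, Sequence[float]],
    max_iter: int = DEFAULT_KMEANS_MAX_ITER,
    tol: float = DEFAULT_KMEANS_TOL,
) -> tuple[ClusterModel, np.ndarray]:
    model = SeededKMeansCpc(seeds=seeds, max_iter=max_iter, tol=tol).fit(features)
    return model.cluster_model_, model.labels_
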