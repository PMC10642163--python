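"""String- and bag-of-words similarity metrics and the weighted-argmax
CPC classifier.

Four metrics are computed between a referral's medical terms and each CPC's
combined text: cosine similarity and Euclidean distance over raw term-count
vectors, Jaccard similarity over term sets, and Levenshtein edit distance
over the space-joined strings (normalized by length so it is comparable to
the bounded metrics). The ensemble score adds the similarities and subtracts
the distances,

    score = w_cos * Cos + w_jac * Jac - w_euc * Euc - w_lev * Lev_norm,

and the predicted CPC is the argmax over the candidate catalog. The weights
are the per-metric categorisation accuracies measured on referrals that
arrived with a valid CPC attached.

Note the ensemble mixes bounded similarities with an unbounded Euclidean
distance; on long documents the Euclidean term can dominate. This follows
the published form of the score; see docs/methods.md.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from math import sqrt
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .catalog import CpcCatalog

TermVector = Counter  # term -> positive count; zero-count terms absent

METRICS = ("cosine", "euclidean", "jaccard", "levenshtein")


def term_vector(tokens: Iterable[str]) -> Counter:
    """Bag-of-terms count vector of a token sequence."""
    return Counter(tokens)


def cosine(a: Counter, b: Counter) -> float:
    """Cosine similarity of two count vectors; 0 if either is empty."""
    if not a or not b:
        return 0.0
    dot = sum(cnt * b[t] for t, cnt in a.items())
    na = sqrt(sum(c * c for c in a.values()))
    nb = sqrt(sum(c * c for c in b.values()))
    return dot / (na * nb)


def euclidean(a: Counter, b: Counter) -> float:
    """Euclidean distance between two count vectors over the union vocabulary."""
    return sqrt(sum((a[t] - b[t]) ** 2 for t in set(a) | set(b)))


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|A∩B| / |A∪B| on term sets; 0 when both sets are empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def levenshtein(a: str, b: str) -> int:
    """Edit distance (insert/delete/substitute, unit costs) via the dynamic-
    programming matrix, vectorized one row at a time."""
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    b_codes = np.frombuffer(b.encode("utf-32-le"), dtype=np.uint32)
    idx = np.arange(lb + 1)
    prev = idx.astype(np.int64)
    cur = np.empty(lb + 1, dtype=np.int64)
    for i, ch in enumerate(a, 1):
        cur[0] = i
        np.minimum(prev[:-1] + (b_codes != ord(ch)), prev[1:] + 1, out=cur[1:])
        # resolve the left-to-right insertion dependency with a prefix min
        np.minimum(cur, np.minimum.accumulate(cur - idx) + idx, out=cur)
        prev, cur = cur, prev
    return int(prev[-1])


def normalized_levenshtein(a: str, b: str, denominator: str = "max_len") -> float:
    """Levenshtein distance scaled into [0, 1].

    ``max_len`` divides by max(len(a), len(b)) — the true maximum possible
    distance; ``sum_len`` divides by len(a) + len(b). Both-empty -> 0.
    """
    if denominator not in ("max_len", "sum_len"):
        raise ValueError(f"unknown denominator {denominator!r}")
    denom = (
        max(len(a), len(b)) if denominator == "max_len" else len(a) + len(b)
    )
    if denom == 0:
        return 0.0
    return levenshtein(a, b) / denom


@dataclass
class SimilarityWeights:
    """Ensemble weights, one per metric; estimated as per-metric accuracies."""

    w_cos: float = 1.0
    w_euc: float = 1.0
    w_jac: float = 1.0
    w_lev: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_cos", "w_euc", "w_jac", "w_lev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def for_metric(cls, metric: str, weight: float = 1.0) -> "SimilarityWeights":
        w = {"w_cos": 0.0, "w_euc": 0.0, "w_jac": 0.0, "w_lev": 0.0}
        w["w_" + {"cosine": "cos", "euclidean": "euc",
                  "jaccard": "jac", "levenshtein": "lev"}[metric]] = weight
        return cls(**w)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"w_cos": self.w_cos, "w_euc": self.w_euc,
                 "w_jac": self.w_jac, "w_lev": self.w_lev},
                fh,
            )

    @classmethod
    def load(cls, path) -> "SimilarityWeights":
        with open(path) as fh:
            return cls(**json.load(fh))


def ensemble_score(
    referral_tokens: Sequence[str],
    cpc_tokens: Sequence[str],
    weights: SimilarityWeights,
    lev_denominator: str = "max_len",
) -> float:
    """Weighted ensemble: similarities added, distances subtracted."""
    a, b = term_vector(referral_tokens), term_vector(cpc_tokens)
    score = 0.0
    if weights.w_cos:
        score += weights.w_cos * cosine(a, b)
    if weights.w_jac:
        score += weights.w_jac * jaccard(referral_tokens, cpc_tokens)
    if weights.w_euc:
        score -= weights.w_euc * euclidean(a, b)
    if weights.w_lev:
        score -= weights.w_lev * normalized_levenshtein(
            " ".join(referral_tokens), " ".join(cpc_tokens), lev_denominator
        )
    return score


def predict_cpc_by_similarity(
    referral_tokens: Sequence[str],
    catalog: CpcCatalog,
    age_group: str,
    representation: str = "keywords",
    weights: SimilarityWeights | None = None,
    lev_denominator: str = "max_len",
) -> tuple[str, dict[str, float]]:
    """Score every CPC's combined text against the referral terms; return
    the argmax cpc_id (ties -> ascending cpc_id) and the full score map."""
    weights = weights or SimilarityWeights()
    entries = catalog.for_age_group(age_group)
    if not entries:
        raise ValueError(f"catalog has no CPC for age group {age_group!r}")
    scores: dict[str, float] = {}
    for entry in entries:  # already sorted by cpc_id -> first max wins ties
        scores[entry.cpc_id] = ensemble_score(
            referral_tokens,
            entry.combined_text(representation),
            weights,
            lev_denominator,
        )
    best_score = max(scores.values())
    best = min(k for k, v in scores.items() if v == best_score)  # tie -> low cpc_id
    return best, scores


class SimilarityCpcClassifier(BaseEstimator, ClassifierMixin):
    """Content-based CPC classifier: nearest CPC description by the weighted
    similarity ensemble. Needs no labeled referrals; ``fit`` validates the
    configuration and, when given labeled data, estimates the metric weights.

    Parameters
    ----------
    catalog : CpcCatalog
    age_group : 'adult' | 'paediatric'
    representation : which CPC text representation to match against.
    weights : SimilarityWeights or None; None with y=None means unit weights.
    lev_denominator : 'max_len' (default) or 'sum_len'.
    """

    def __init__(
        self,
        catalog: CpcCatalog | None = None,
        age_group: str = "adult",
        representation: str = "keywords",
        weights: SimilarityWeights | None = None,
        lev_denominator: str = "max_len",
    ):
        self.catalog = catalog
        self.age_group = age_group
        self.representation = representation
        self.weights = weights
        self.lev_denominator = lev_denominator

    def fit(self, X: Sequence[Sequence[str]] | None = None, y=None):
        """X: token sequences of referrals with a known historical category
        (only used for weight estimation); y: their categories."""
        if self.catalog is None:
            raise ValueError("catalog is required")
        entries = self.catalog.for_age_group(self.age_group)
        if not entries:
            raise ValueError(f"no CPC for age group {self.age_group!r}")
        self.classes_ = np.array([e.cpc_id for e in entries])
        if self.weights is not None:
            self.weights_ = self.weights
        elif X is not None and y is not None:
            self.weights_ = estimate_weights_from_terms(
                list(X), list(y), self.catalog, self.age_group, self.representation
            )
        else:
            self.weights_ = SimilarityWeights()
        return self

    def predict(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        self._check_fitted()
        return np.array([self._predict_one(tokens)[0] for tokens in X])

    def score_maps(self, X: Sequence[Sequence[str]]) -> list[dict[str, float]]:
        self._check_fitted()
        return [self._predict_one(tokens)[1] for tokens in X]

    def _predict_one(self, tokens):
        return predict_cpc_by_similarity(
            list(tokens),
            self.catalog,
            self.age_group,
            self.representation,
            self.weights_,
            self.lev_denominator,
        )

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise ValueError("classifier is not fitted; call fit() first")


def estimate_weights_from_terms(
    term_lists: list[list[str]],
    categories: list[int],
    catalog: CpcCatalog,
    age_group: str,
    representation: str = "keywords",
    cpc_ids: list[str] | None = None,
) -> SimilarityWeights:
    """Per-metric ensemble weights = each metric's categorisation accuracy on
    referrals whose CPC is known.

    For each metric alone, the category-assignment path is run (on the given
    CPC when supplied, else on the metric's own CPC prediction) and the weight
    is the fraction of categories matching the historical category.
    """
    from .triage import assign_category  # local import: triage builds on this module

    if not term_lists:
        raise ValueError("weight estimation requires a non-empty labeled set")
    if len(term_lists) != len(categories):
        raise ValueError("term_lists and categories must align")
    acc = {}
    for metric in METRICS:
        correct = 0
        for i, (terms, cat) in enumerate(zip(term_lists, categories)):
            if cpc_ids is not None:
                entry = catalog.get(cpc_ids[i], age_group)
            else:
                cid, _ = predict_cpc_by_similarity(
                    terms, catalog, age_group, representation,
                    SimilarityWeights.for_metric(metric),
                )
                entry = catalog.get(cid, age_group)
            pred_cat, _ = assign_category(terms, entry, representation, metric)
            if pred_cat == cat:
                correct += 1
        acc[metric] = correct / len(term_lists)
    weights = SimilarityWeights(
        w_cos=acc["cosine"], w_euc=acc["euclidean"],
        w_jac=acc["jaccard"], w_lev=acc["levenshtein"],
    )
    if all(v == 0.0 for v in acc.values()):
        warnings.warn(
            "all four similarity metrics scored zero accuracy; the resulting "
            "all-zero weights are unusable for classification",
            UserWarning,
            stacklevel=2,
        )
    return weights


def estimate_weights(
    labeled_referrals,
    catalog: CpcCatalog,
    representation: str = "keywords",
    age_group: str = "adult",
    threshold: float = 0.5,
) -> SimilarityWeights:
    """Convenience wrapper over Referral objects carrying a validated CPC
    label and a historical category."""
    from .catalog import validate_cpc_label
    from .preprocess import referral_terms

    terms, cats, cpcs = [], [], []
    for ref in labeled_referrals:
        cid = validate_cpc_label(ref.raw_cpc_label, catalog, age_group)
        if cid is None or ref.historical_category is None:
            raise ValueError(
                f"{ref.referral_id}: weight estimation needs a valid CPC label "
                "and a historical category"
            )
        terms.append(referral_terms(ref))
        cats.append(ref.historical_category)
        cpcs.append(cid)
    return estimate_weights_from_terms(
        terms, cats, catalog, age_group, representation, cpc_ids=cpcs
    )
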