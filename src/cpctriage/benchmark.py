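"""Run any CPC-prediction family through the full triage flow and sweep
method x representation x metric grids.

Referrals that arrive with a valid CPC label keep it ("given"); the rest
receive a predicted CPC from the chosen family. Categories are then assigned
from the per-category CPC units with the chosen metric, and the level of
agreement is measured against historical categories (or generator ground
truth on synthetic corpora).
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .catalog import CpcCatalog, validate_cpc_label
from .features import TermCountVectorizer
from .predictors import (
    NO_PREDICTION,
    vectorize_seeds,
    ClassifierSpec,
    KnnCpcClassifier,
    SeededKMeansCpc,
    SelfTrainingCpcClassifier,
    SupervisedCpcClassifier,
)
from .preprocess import Referral, age_group as resolve_age_group, referral_terms
from .similarity import SimilarityWeights, predict_cpc_by_similarity
from .triage import TriageResult, assign_category

logger = logging.getLogger(__name__)

METHOD_FAMILIES = ("similarity", "knn", "supervised", "semi_supervised", "kmeans")


def triage_with_method(
    referrals: Sequence[Referral],
    catalog: CpcCatalog,
    method: str = "similarity",
    representation: str = "keywords",
    metric: str = "levenshtein",
    weights: SimilarityWeights | None = None,
    seed: int = 0,
    min_doc_count: int = 1,
    max_doc_fraction: float = 1.0,
    knn_k: int = 10,
    classifier_spec: ClassifierSpec | None = None,
    pseudo_label_threshold: float = 0.75,
    age_cutoff: int = 16,
) -> tuple[list[TriageResult], list[tuple[str, str]]]:
    """Full triage of a corpus with one CPC-prediction family.

    The trainable families (knn, supervised, semi_supervised) learn from the
    referrals whose attached CPC label validates; kmeans is unsupervised with
    catalog-seeded centroids. Feature-filter defaults are relaxed relative to
    the large-corpus defaults because training corpora here may be small.
    """
    if method not in METHOD_FAMILIES:
        raise ValueError(f"unknown method {method!r}; one of {METHOD_FAMILIES}")
    n = len(referrals)
    terms = [referral_terms(r) for r in referrals]
    groups = [
        resolve_age_group(r.date_of_birth, r.submission_date, age_cutoff)
        for r in referrals
    ]
    given: dict[int, str | None] = {
        i: validate_cpc_label(referrals[i].raw_cpc_label, catalog, groups[i])
        for i in range(n)
    }
    predicted: dict[int, str] = {}
    failures: list[tuple[str, str]] = []

    for group in ("adult", "paediatric"):
        idx = [i for i in range(n) if groups[i] == group]
        need = [i for i in idx if given[i] is None]
        if not need:
            continue
        if method == "similarity":
            w = weights or SimilarityWeights()  # default: full unit-weight ensemble
            for i in need:
                predicted[i], _ = predict_cpc_by_similarity(
                    terms[i], catalog, group, representation, w
                )
            continue
        vec = TermCountVectorizer(min_doc_count, max_doc_fraction)
        group_entries = catalog.for_age_group(group)
        if method == "kmeans":
            # the seed texts must embed in the feature space, so the catalog
            # texts join the referral corpus for vocabulary fitting
            vec.fit(
                [terms[i] for i in idx]
                + [e.combined_text(representation) for e in group_entries]
            )
        else:
            vec.fit([terms[i] for i in idx])
        X_need = vec.transform([terms[i] for i in need])
        labeled = [i for i in idx if given[i] is not None]
        if method == "kmeans":
            seeds = vectorize_seeds(
                vec,
                {
                    e.cpc_id: e.combined_text(representation)
                    for e in group_entries
                },
            )
            model = SeededKMeansCpc(seeds=seeds)
            model.fit(vec.transform([terms[i] for i in idx]))
            preds = model.predict(X_need)
        else:
            if not labeled:
                for i in need:
                    failures.append(
                        (referrals[i].referral_id,
                         f"no labeled {group} referrals to train {method}")
                    )
                continue
            X_lab = vec.transform([terms[i] for i in labeled])
            y_lab = [given[i] for i in labeled]
            if method == "knn":
                model = KnnCpcClassifier(k=knn_k).fit(X_lab, y_lab)
            elif method == "supervised":
                model = SupervisedCpcClassifier(
                    spec=classifier_spec, seed=seed
                ).fit(X_lab, y_lab)
            else:  # semi_supervised
                model = SelfTrainingCpcClassifier(
                    spec=classifier_spec,
                    threshold=pseudo_label_threshold,
                    seed=seed,
                ).fit(X_lab, y_lab, X_unlabeled=X_need)
            preds = model.predict(X_need)
        for i, p in zip(need, preds):
            predicted[i] = str(p)

    results: list[TriageResult] = []
    for i in range(n):
        cpc_id = given[i] if given[i] is not None else predicted.get(i)
        if cpc_id is None:
            continue  # failure already recorded
        if cpc_id == NO_PREDICTION:
            failures.append(
                (referrals[i].referral_id, "no neighbour with similarity > 0")
            )
            continue
        try:
            entry = catalog.get(cpc_id, groups[i])
            category, scores = assign_category(
                terms[i], entry, representation, metric
            )
        except ValueError as exc:
            failures.append((referrals[i].referral_id, str(exc)))
            continue
        results.append(
            TriageResult(
                referral_id=referrals[i].referral_id,
                age_group=groups[i],
                cpc_id=cpc_id,
                cpc_source="given" if given[i] is not None else "predicted",
                cpc_method=None if given[i] is not None else method,
                category=category,
                category_scores=scores,
            )
        )
    return results, failures


def agreement_against(
    results: Sequence[TriageResult], reference: dict[str, int]
) -> float:
    """Fraction of triaged referrals whose category matches the reference."""
    if not results:
        raise ValueError("no results to compare")
    hits = sum(1 for r in results if reference.get(r.referral_id) == r.category)
    return hits / len(results)


def cpc_agreement_against(
    results: Sequence[TriageResult], reference: dict[str, str]
) -> float:
    """Fraction whose resolved CPC matches the reference CPC."""
    if not results:
        raise ValueError("no results to compare")
    hits = sum(1 for r in results if reference.get(r.referral_id) == r.cpc_id)
    return hits / len(results)


def run_benchmark(
    referrals: Sequence[Referral],
    catalog: CpcCatalog,
    methods: Sequence[str] = ("similarity", "kmeans"),
    representations: Sequence[str] = ("criteria_words", "medical_terms", "keywords"),
    metrics: Sequence[str] = ("cosine", "euclidean", "jaccard", "levenshtein"),
    reference: dict[str, int] | None = None,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Sweep the (method family x CPC representation x metric) grid and
    report each cell's level of agreement; failed cells record NA."""
    if reference is None:
        reference = {
            r.referral_id: r.historical_category
            for r in referrals
            if r.historical_category is not None
        }
    rows = []
    for method in methods:
        for rep in representations:
            for metric in metrics:
                try:
                    cell_weights = (
                        SimilarityWeights.for_metric(metric)
                        if method == "similarity"
                        else None
                    )
                    results, _ = triage_with_method(
                        referrals, catalog, method=method, representation=rep,
                        metric=metric, weights=cell_weights, seed=seed, **kwargs,
                    )
                    value = agreement_against(results, reference)
                    n_cell = len(results)
                except (ValueError, RuntimeError) as exc:
                    logger.warning(
                        "benchmark cell (%s, %s, %s) failed: %s",
                        method, rep, metric, exc,
                    )
                    value, n_cell = float("nan"), 0
                rows.append(
                    {
                        "method": method,
                        "representation": rep,
                        "metric": metric,
                        "agreement": value,
                        "n": n_cell,
                    }
                )
    return pd.DataFrame(rows)
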