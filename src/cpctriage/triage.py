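"""End-to-end referral triage and its evaluation.

Flow per referral: check whether an attached CPC label validates against the
age-group catalog; if not, predict the CPC with the configured predictor;
then assign the urgency category by comparing the referral's medical terms
with the CPC's per-category text units (a CPC with a mandatory category, such
as adult head-and-neck mass, forces category 1 regardless of text).

Evaluation reports the *level of agreement* with historically assigned
categories — not accuracy, because the historical labels are themselves a
noisy reference — plus a 3x3 confusion matrix and per-category precision and
sensitivity with unweighted macro averages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .catalog import CATEGORIES, CpcCatalog, CpcDefinition, validate_cpc_label
from .preprocess import Referral, age_group as resolve_age_group, referral_terms
from .similarity import (
    METRICS,
    SimilarityWeights,
    normalized_levenshtein,
    cosine,
    euclidean,
    jaccard,
    predict_cpc_by_similarity,
    term_vector,
)

logger = logging.getLogger(__name__)

DEFAULT_REPRESENTATION = "keywords"
DEFAULT_CATEGORY_METRIC = "levenshtein"


class TriageError(RuntimeError):
    pass


@dataclass
class TriageResult:
    referral_id: str
    age_group: str
    cpc_id: str
    cpc_source: str  # given | predicted
    cpc_method: str | None
    category: int
    category_scores: dict[int, float]

    def __post_init__(self) -> None:
        if self.cpc_source == "given" and self.cpc_method is not None:
            raise ValueError("cpc_method must be absent when the CPC was given")


@dataclass
class AgreementReport:
    n: int
    agreement: float
    confusion: np.ndarray  # rows actual, columns predicted, categories 1..3
    per_category: dict[int, dict[str, float]]
    overall_precision: float
    overall_sensitivity: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "agreement": self.agreement,
            "confusion": self.confusion.tolist(),
            "per_category": {
                str(c): vals for c, vals in self.per_category.items()
            },
            "overall_precision": self.overall_precision,
            "overall_sensitivity": self.overall_sensitivity,
            "accuracy": self.accuracy,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _unit_score(terms: Sequence[str], unit: Sequence[str], metric: str) -> float:
    """Higher-is-better score of a referral against one category unit.

    Similarities are used as-is; distances are negated (Levenshtein after
    length normalization) so the best category maximizes the score.
    """
    if metric == "cosine":
        return cosine(term_vector(terms), term_vector(unit))
    if metric == "jaccard":
        return jaccard(terms, unit)
    if metric == "euclidean":
        return -euclidean(term_vector(terms), term_vector(unit))
    if metric == "levenshtein":
        return -normalized_levenshtein(" ".join(terms), " ".join(unit))
    raise ValueError(f"unknown metric {metric!r}; one of {METRICS}")


def assign_category(
    referral_terms_seq: Sequence[str],
    cpc: CpcDefinition,
    representation: str = DEFAULT_REPRESENTATION,
    metric: str = DEFAULT_CATEGORY_METRIC,
) -> tuple[int, dict[int, float]]:
    """Pick the urgency category whose CPC text unit best matches the
    referral terms; mandatory-category CPCs short-circuit; ties break toward
    the more urgent (lower) category."""
    if cpc.fixed_category is not None:
        return cpc.fixed_category, {cpc.fixed_category: 0.0}
    units = cpc.category_units(representation)
    scores: dict[int, float] = {}
    for cat in CATEGORIES:
        unit = units.get(cat, [])
        if unit:
            scores[cat] = _unit_score(list(referral_terms_seq), unit, metric)
    if not scores:
        raise ValueError(
            f"{cpc.cpc_id}: every category unit of representation "
            f"{representation!r} is empty"
        )
    best = max(scores.values())
    category = min(c for c, s in scores.items() if s == best)
    return category, scores


@dataclass
class TriageConfig:
    """End-to-end configuration: which CPC predictor to use, which CPC text
    representation, which metric scores categories, and the ensemble weights
    for the similarity predictor."""

    representation: str = DEFAULT_REPRESENTATION
    category_metric: str = DEFAULT_CATEGORY_METRIC
    weights: SimilarityWeights = field(default_factory=SimilarityWeights)
    predictor: str = "similarity"
    age_cutoff: int = 16
    #: optional map age_group -> callable(terms) -> cpc_id, for the trainable
    #: predictor families; the similarity predictor needs no such hook.
    predictor_fn: dict[str, Callable[[Sequence[str]], str]] | None = None


def resolve_cpc(
    referral: Referral,
    catalog: CpcCatalog,
    config: TriageConfig,
    terms: Sequence[str] | None = None,
    group: str | None = None,
) -> tuple[str, str, str | None]:
    """(cpc_id, source, method): the given CPC when the attached label
    validates for the referral's age group, otherwise the configured
    predictor's output."""
    if group is None:
        group = resolve_age_group(
            referral.date_of_birth, referral.submission_date, config.age_cutoff
        )
    given = validate_cpc_label(referral.raw_cpc_label, catalog, group)
    if given is not None:
        return given, "given", None
    if terms is None:
        terms = referral_terms(referral)
    if config.predictor_fn is not None:
        cpc_id = config.predictor_fn[group](terms)
        method = config.predictor
    else:
        cpc_id, _ = predict_cpc_by_similarity(
            list(terms), catalog, group, config.representation, config.weights
        )
        method = "similarity"
    if cpc_id is None or cpc_id.startswith("__no_prediction"):
        raise TriageError(f"{referral.referral_id}: predictor returned no CPC")
    return cpc_id, "predicted", method


def triage_batch(
    referrals: Sequence[Referral],
    catalog: CpcCatalog,
    config: TriageConfig | None = None,
) -> tuple[list[TriageResult], list[tuple[str, str]]]:
    """Triage a batch; per-referral failures are collected (id, reason) and
    the batch continues."""
    config = config or TriageConfig()
    results: list[TriageResult] = []
    failures: list[tuple[str, str]] = []
    for ref in referrals:
        try:
            group = resolve_age_group(
                ref.date_of_birth, ref.submission_date, config.age_cutoff
            )
            terms = referral_terms(ref)
            cpc_id, source, method = resolve_cpc(
                ref, catalog, config, terms=terms, group=group
            )
            entry = catalog.get(cpc_id, group)
            category, scores = assign_category(
                terms, entry, config.representation, config.category_metric
            )
            results.append(
                TriageResult(
                    referral_id=ref.referral_id,
                    age_group=group,
                    cpc_id=cpc_id,
                    cpc_source=source,
                    cpc_method=method,
                    category=category,
                    category_scores=scores,
                )
            )
            logger.debug(
                "triage %s: %s cpc=%s (%s) category=%d",
                ref.referral_id, group, cpc_id, source, category,
            )
        except (ValueError, TriageError, KeyError) as exc:
            failures.append((ref.referral_id, str(exc)))
            logger.warning("triage %s failed: %s", ref.referral_id, exc)
    logger.info(
        "triage batch: %d ok (%d given, %d predicted), %d failed",
        len(results),
        sum(r.cpc_source == "given" for r in results),
        sum(r.cpc_source == "predicted" for r in results),
        len(failures),
    )
    return results, failures


def results_to_frame(results: Sequence[TriageResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "referral_id": r.referral_id,
            "age_group": r.age_group,
            "cpc_id": r.cpc_id,
            "cpc_source": r.cpc_source,
            "cpc_method": r.cpc_method,
            "category": r.category,
        }
        for c in CATEGORIES:
            row[f"score_cat{c}"] = r.category_scores.get(c)
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate(
    results: Sequence[TriageResult], historical: dict[str, int]
) -> AgreementReport:
    """Level of agreement between predicted and historical categories, with
    the 3x3 confusion matrix and per-category precision/sensitivity."""
    if not results:
        raise ValueError("cannot evaluate an empty result list")
    pairs = []
    for r in results:
        if r.referral_id not in historical:
            raise ValueError(f"no historical category for {r.referral_id}")
        pairs.append((historical[r.referral_id], r.category))
    return agreement_report(
        [a for a, _ in pairs], [p for _, p in pairs]
    )


def agreement_report(
    actual: Sequence[int], predicted: Sequence[int]
) -> AgreementReport:
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    n = len(actual)
    if n == 0:
        raise ValueError("cannot evaluate zero records")
    confusion = np.zeros((3, 3), dtype=int)
    for a, p in zip(actual, predicted):
        confusion[a - 1, p - 1] += 1
    trace = int(np.trace(confusion))
    per_category: dict[int, dict[str, float]] = {}
    for c in CATEGORIES:
        tp = confusion[c - 1, c - 1]
        col = confusion[:, c - 1].sum()
        row = confusion[c - 1, :].sum()
        per_category[c] = {
            "precision": float(tp / col) if col else 0.0,
            "sensitivity": float(tp / row) if row else 0.0,
        }
    return AgreementReport(
        n=n,
        agreement=trace / n,
        confusion=confusion,
        per_category=per_category,
        overall_precision=float(
            np.mean([per_category[c]["precision"] for c in CATEGORIES])
        ),
        overall_sensitivity=float(
            np.mean([per_category[c]["sensitivity"] for c in CATEGORIES])
        ),
        accuracy=trace / n,
    )
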