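"""Referral ingestion and text preprocessing.

Turns raw referral text and extracted medical-entity files (Comprehend-
Medical-style JSON) into cleaned, stemmed medical-term token sequences, and
resolves each referral's age group from date of birth and submission date
(cutoff 16 years: under 16 is paediatric).

Entity filtering keeps entities scoring >= 0.5 whose (category, type) pair is
in the clinically curated allow-list: diagnosis names, generic/brand
medication names, treatment/procedure names, and anatomical directions.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from ._porter import porter_stem

#: (category, type) pairs of medical entities retained as medical terms.
DEFAULT_ENTITY_TYPES: frozenset[tuple[str, str]] = frozenset(
    {
        ("Medical_Condition", "DX_Name"),
        ("Medication", "Generic_Name"),
        ("Medication", "Brand_Name"),
        ("Test_Treatment_Procedure", "Treatment_Name"),
        ("Test_Treatment_Procedure", "Procedure_Name"),
        ("Anatomy", "Direction"),
    }
)

DEFAULT_ENTITY_SCORE = 0.5
DEFAULT_AGE_CUTOFF = 16
DEFAULT_STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)

_NON_ALPHA = re.compile(r"[^a-z\s]+")


@dataclass
class EntityRecord:
    """One extracted medical entity with the extractor's confidence score."""

    text: str
    category: str
    type: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"entity score must be in [0, 1], got {self.score}")


@dataclass
class Referral:
    """One referral letter and its metadata."""

    referral_id: str
    raw_text: str = ""
    entities: list[EntityRecord] = field(default_factory=list)
    medical_terms: list[str] = field(default_factory=list)
    date_of_birth: dt.date | None = None
    submission_date: dt.date | None = None
    raw_cpc_label: str | None = None
    historical_category: int | None = None
    lodgment: str | None = None

    def __post_init__(self) -> None:
        if (
            self.date_of_birth is not None
            and self.submission_date is not None
            and self.submission_date < self.date_of_birth
        ):
            raise ValueError(
                f"{self.referral_id}: submission_date precedes date_of_birth"
            )
        if self.historical_category is not None and self.historical_category not in (
            1,
            2,
            3,
        ):
            raise ValueError(
                f"{self.referral_id}: historical_category must be 1, 2 or 3"
            )


def clean_tokens(
    text: str, stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS
) -> list[str]:
    """Lowercase, strip everything outside [a-z] and whitespace, drop
    stopwords, Porter-stem each remaining token. Order preserved."""
    lowered = _NON_ALPHA.sub("", text.lower())
    return [porter_stem(tok) for tok in lowered.split() if tok not in stopwords]


def filter_entities(
    entities: list[EntityRecord],
    threshold: float = DEFAULT_ENTITY_SCORE,
    allowed: frozenset[tuple[str, str]] | set[tuple[str, str]] = DEFAULT_ENTITY_TYPES,
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> list[str]:
    """Medical terms from entities scoring >= threshold (boundary inclusive)
    with an allowed (category, type), cleaned and stemmed, input order kept."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    out: list[str] = []
    for ent in entities:
        if ent.score >= threshold and (ent.category, ent.type) in allowed:
            out.extend(clean_tokens(ent.text, stopwords))
    return out


def extract_entities_lexicon(
    text: str, lexicon: dict[str, tuple[str, str]]
) -> list[EntityRecord]:
    """Deterministic dictionary-based entity extractor.

    Pluggable stand-in for an NER service: emits one EntityRecord (score 1.0)
    per case-insensitive, non-overlapping occurrence of a lexicon term,
    longest match first.
    """
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    lowered = text.lower()
    taken = [False] * len(text)
    spans: list[tuple[int, str]] = []
    for term in sorted(lexicon, key=len, reverse=True):
        start = 0
        t = term.lower()
        while True:
            idx = lowered.find(t, start)
            if idx < 0:
                break
            end = idx + len(t)
            if not any(taken[idx:end]):
                for i in range(idx, end):
                    taken[i] = True
                spans.append((idx, term))
            start = idx + 1
    spans.sort()
    return [
        EntityRecord(text=text[i : i + len(term)], category=lexicon[term][0],
                     type=lexicon[term][1], score=1.0)
        for i, term in spans
    ]


def age_in_years(date_of_birth: dt.date, submission_date: dt.date) -> int:
    """Completed years of age at the submission date."""
    if submission_date < date_of_birth:
        raise ValueError("submission date precedes date of birth")
    years = submission_date.year - date_of_birth.year
    if (submission_date.month, submission_date.day) < (
        date_of_birth.month,
        date_of_birth.day,
    ):
        years -= 1
    return years


def age_group(
    date_of_birth: dt.date,
    submission_date: dt.date,
    cutoff_years: int = DEFAULT_AGE_CUTOFF,
) -> str:
    """'paediatric' when age < cutoff at submission, else 'adult'
    (the exact 16th birthday counts as adult)."""
    return (
        "paediatric"
        if age_in_years(date_of_birth, submission_date) < cutoff_years
        else "adult"
    )


def referral_terms(
    referral: Referral,
    threshold: float = DEFAULT_ENTITY_SCORE,
    allowed=DEFAULT_ENTITY_TYPES,
    stopwords=DEFAULT_STOPWORDS,
) -> list[str]:
    """Medical terms for one referral: filtered entities when any survive,
    otherwise the cleaned raw text (degraded fallback so similarity is never
    computed on an empty document)."""
    terms = filter_entities(referral.entities, threshold, allowed, stopwords)
    if not terms:
        terms = clean_tokens(referral.raw_text, stopwords)
    return terms


# ---------------------------------------------------------------------------
# File ingestion


def _parse_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value)[:10])


def load_entity_file(path) -> dict[str, list[EntityRecord]]:
    """Read a Comprehend-Medical-style entity JSON file.

    Accepts either ``{"Entities": [...]}`` (one referral per file; keyed by
    the file stem) or ``{referral_id: {"Entities": [...]}, ...}``.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)

    def records(block) -> list[EntityRecord]:
        return [
            EntityRecord(
                text=e["Text"], category=e["Category"], type=e["Type"],
                score=float(e["Score"]),
            )
            for e in block.get("Entities", [])
        ]

    if "Entities" in data:
        return {path.stem: records(data)}
    return {rid: records(block) for rid, block in data.items()}


def load_referrals(
    path,
    entities: dict[str, list[EntityRecord]] | None = None,
) -> list[Referral]:
    """Read a referral table (CSV, or JSON-lines when the suffix is .jsonl)
    with columns referral_id, text, dob, submitted, cpc_label, category,
    lodgment; attach entity records when provided."""
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        df = pd.read_json(path, lines=True, dtype={"referral_id": str})
    else:
        df = pd.read_csv(path, dtype={"referral_id": str})
    required = {"referral_id", "text"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"referral table missing columns: {sorted(missing)}")
    out = []
    entities = entities or {}
    for row in df.to_dict("records"):
        cat = row.get("category")
        cat = int(cat) if cat is not None and not pd.isna(cat) else None
        label = row.get("cpc_label")
        if label is not None and (not isinstance(label, str)) and pd.isna(label):
            label = None
        rid = str(row["referral_id"])
        out.append(
            Referral(
                referral_id=rid,
                raw_text=str(row.get("text", "") or ""),
                entities=entities.get(rid, []),
                date_of_birth=_parse_date(row.get("dob")),
                submission_date=_parse_date(row.get("submitted")),
                raw_cpc_label=label,
                historical_category=cat,
                lodgment=row.get("lodgment") or None,
            )
        )
    return out
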