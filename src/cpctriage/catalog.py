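"""Clinical Prioritisation Criteria (CPC) catalog.

A CPC catalog describes, per clinical condition and age group (adult vs
paediatric), the text that places a referral in urgency category 1, 2 or 3.
Each condition carries up to three text representations:

- ``criteria_words`` — the cleaned full criteria text,
- ``medical_terms`` — medical entities extracted from the criteria,
- ``keywords``      — clinician-curated keywords.

Each representation is split by category; the three category units are used
separately for category prediction and concatenated ("combined unit") for
CPC prediction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable

AGE_GROUPS = ("adult", "paediatric")
REPRESENTATIONS = ("criteria_words", "medical_terms", "keywords")
CATEGORIES = (1, 2, 3)

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


class CatalogError(ValueError):
    """Malformed or inconsistent CPC catalog."""


def normalize_label(label: str) -> str:
    """Normalize a condition name / raw CPC label for exact matching:
    lowercase, punctuation stripped, whitespace collapsed."""
    label = _PUNCT_RE.sub(" ", label.lower())
    return _WS_RE.sub(" ", label).strip()


@dataclass
class CpcDefinition:
    """One CPC condition for one age group."""

    cpc_id: str
    age_group: str
    condition_name: str
    representations: dict[str, dict[int, list[str]]]
    fixed_category: int | None = None

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise CatalogError(
                f"{self.cpc_id}: age_group must be one of {AGE_GROUPS}, "
                f"got {self.age_group!r}"
            )
        if self.fixed_category is not None and self.fixed_category not in CATEGORIES:
            raise CatalogError(
                f"{self.cpc_id}: fixed_category must be in {CATEGORIES}"
            )
        for rep, units in self.representations.items():
            if rep not in REPRESENTATIONS:
                raise CatalogError(f"{self.cpc_id}: unknown representation {rep!r}")
            if not any(units.get(c) for c in CATEGORIES):
                raise CatalogError(
                    f"{self.cpc_id}: representation {rep!r} has no non-empty "
                    "category unit"
                )

    def combined_text(self, representation: str) -> list[str]:
        """Category units concatenated in ascending category order (1, 2, 3)."""
        units = self._units(representation)
        out: list[str] = []
        for cat in CATEGORIES:
            out.extend(units.get(cat, []))
        return out

    def category_units(self, representation: str) -> dict[int, list[str]]:
        return {c: list(self._units(representation).get(c, [])) for c in CATEGORIES}

    def _units(self, representation: str) -> dict[int, list[str]]:
        try:
            return self.representations[representation]
        except KeyError:
            raise CatalogError(
                f"{self.cpc_id}: representation {representation!r} not available"
            ) from None


@dataclass
class CpcCatalog:
    """All CPC definitions, both age groups."""

    entries: list[CpcDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        for group in AGE_GROUPS:
            ids = [e.cpc_id for e in self.entries if e.age_group == group]
            dup = {i for i in ids if ids.count(i) > 1}
            if dup:
                raise CatalogError(
                    f"duplicate cpc_id within {group} group: {sorted(dup)}"
                )

    @property
    def adult_count(self) -> int:
        return sum(1 for e in self.entries if e.age_group == "adult")

    @property
    def paediatric_count(self) -> int:
        return sum(1 for e in self.entries if e.age_group == "paediatric")

    def for_age_group(self, age_group: str) -> list[CpcDefinition]:
        if age_group not in AGE_GROUPS:
            raise CatalogError(f"unknown age group {age_group!r}")
        return sorted(
            (e for e in self.entries if e.age_group == age_group),
            key=lambda e: e.cpc_id,
        )

    def get(self, cpc_id: str, age_group: str) -> CpcDefinition:
        for e in self.entries:
            if e.cpc_id == cpc_id and e.age_group == age_group:
                return e
        raise CatalogError(f"unknown cpc_id {cpc_id!r} for age group {age_group!r}")

    def to_dict(self) -> dict:
        out: dict[str, list] = {g: [] for g in AGE_GROUPS}
        for e in self.entries:
            out[e.age_group].append(
                {
                    "cpc_id": e.cpc_id,
                    "condition_name": e.condition_name,
                    "fixed_category": e.fixed_category,
                    "representations": {
                        rep: {str(c): list(toks) for c, toks in units.items()}
                        for rep, units in e.representations.items()
                    },
                }
            )
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _parse_entry(raw: dict, age_group: str) -> CpcDefinition:
    try:
        reps = {
            rep: {int(c): list(toks) for c, toks in units.items()}
            for rep, units in raw["representations"].items()
        }
        return CpcDefinition(
            cpc_id=raw["cpc_id"],
            age_group=age_group,
            condition_name=raw["condition_name"],
            representations=reps,
            fixed_category=raw.get("fixed_category"),
        )
    except (KeyError, TypeError, AttributeError) as exc:
        name = raw.get("cpc_id", "<missing cpc_id>") if isinstance(raw, dict) else raw
        raise CatalogError(f"malformed catalog entry {name!r}: {exc}") from exc


def catalog_from_dict(data: dict) -> CpcCatalog:
    entries = []
    for group in AGE_GROUPS:
        for raw in data.get(group, []):
            entries.append(_parse_entry(raw, group))
    return CpcCatalog(entries)


def load_catalog(path) -> CpcCatalog:
    """Load and validate a JSON CPC catalog file."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CatalogError(f"cannot parse catalog file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise CatalogError(f"catalog file {path} must contain a JSON object")
    return catalog_from_dict(data)


def cpc_text(
    catalog: CpcCatalog,
    cpc_id: str,
    age_group: str,
    representation: str,
    unit: str = "combined",
):
    """Text of one CPC: ``combined`` (one token sequence, categories 1,2,3
    concatenated) or ``per_category`` (map category -> token sequence)."""
    entry = catalog.get(cpc_id, age_group)
    if unit == "combined":
        return entry.combined_text(representation)
    if unit == "per_category":
        return entry.category_units(representation)
    raise CatalogError(f"unit must be 'combined' or 'per_category', got {unit!r}")


def validate_cpc_label(
    raw_label: str | None, catalog: CpcCatalog, age_group: str
) -> str | None:
    """Exact membership check of a raw CPC label against one age group's
    conditions, after normalization. Returns the cpc_id or None; a referral
    whose label does not validate proceeds to CPC prediction."""
    if not raw_label:
        return None
    wanted = normalize_label(raw_label)
    if not wanted:
        return None
    for entry in catalog.for_age_group(age_group):
        if normalize_label(entry.condition_name) == wanted:
            return entry.cpc_id
    return None


def make_catalog(entries: Iterable[CpcDefinition]) -> CpcCatalog:
    return CpcCatalog(list(entries))
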