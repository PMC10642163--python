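"""Synthetic CPC catalogs and referral corpora.

No real referral data can be distributed (clinical privacy), so this module
generates corpora with the statistical structure the triage method assumes:

- a catalog of ENT conditions per age group (20 adult, 13 paediatric by
  default, carrying the published labeled-set class frequencies, including
  zero-frequency conditions),
- per-condition core vocabularies, disjoint between conditions, split across
  urgency categories 1/2/3 (the clinician-keyword representation), extended
  with morphological variants (medical-terms representation) and shared
  filler words (criteria-words representation),
- referrals whose terms mix their true condition/category vocabulary with
  background noise, with single-character typos injected at a configurable
  rate (emulating variants like "blocked"/"blockage"/"blockednose"),
- a configurable labeled fraction (default 9.7%) and a configurable
  disagreement rate between the category implied by the CPC and the
  historically assigned category.

Generated vocabulary words are fixed points of the Porter stemmer, so the
preprocessing pipeline leaves catalog and referral terms aligned.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._porter import porter_stem
from .catalog import CATEGORIES, CpcCatalog, CpcDefinition
from .preprocess import DEFAULT_STOPWORDS, EntityRecord, Referral

#: Published labeled-set frequencies per ENT condition (adult).
ADULT_CPC_FREQUENCIES: dict[str, int] = {
    "Allergic rhinitis/nasal congestion/obstruction": 0,
    "chronic ear disease": 82,
    "dizziness/vertigo": 37,
    "dysphagia": 103,
    "dysphonia": 124,
    "ear drum perforation": 20,
    "epistaxis (recurrent)": 31,
    "facial nerve palsy": 2,
    "head and neck mass": 100,
    "hearing loss": 180,
    "nasal fracture (acute)": 28,
    "obstructive sleep apnoea": 42,
    "oropharyngeal lesions": 47,
    "primary parathyroid adenoma": 3,
    "rhinosinusitis (chronic/recurrent)": 214,
    "salivary tumour": 13,
    "sialolithiasis (salivary stones)": 10,
    "thyroid mass": 27,
    "tinnitus": 45,
    "tonsillitis (recurrent) or tonsillar enlargement": 127,
}

#: Published labeled-set frequencies per ENT condition (paediatric).
PAEDIATRIC_CPC_FREQUENCIES: dict[str, int] = {
    "dysphonia/hoarseness": 4,
    "epistaxis (recurrent)": 5,
    "hearing loss": 24,
    "Nasal allergic rhinitis/congestion/obstruction": 0,
    "Nasal fracture (acute)": 0,
    "Neck mass": 0,
    "otitis externa": 3,
    "Otitis media (acute, with or without perforation)": 0,
    "Otitis media with effusion (glue ear)": 0,
    "perforated eardrum/chronic suppurative otitis media": 5,
    "sleep disordered breathing/obstructive sleep apnoea": 36,
    "stridor": 3,
    "tonsillitis (recurrent)": 50,
}

#: Adult conditions whose criteria mandate a single category.
FIXED_CATEGORY_CONDITIONS = {"head and neck mass": 1}

_CONSONANTS = "bdfgklmnprtvz"
_VOWELS_MID = "aeiou"
_VOWELS_END = "aiou"  # no trailing 'e_' digraphs like "ed"
_SAFE_FINALS = "bdfgkmprtvz"


def slugify(name: str) -> str:
    out = []
    prev_dash = True
    for ch in name.lower():
        if ch.isalnum():
            out.append(ch)
            prev_dash = False
        elif not prev_dash:
            out.append("-")
            prev_dash = True
    return "".join(out).strip("-")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults carry the published setting: 20 adult / 13 paediatric CPCs, a
    9.7% labeled fraction, the published class-frequency profile, and an
    adult share of ~2/3 of referrals.
    """

    seed: int = 0
    n_adult_cpcs: int = 20
    n_paediatric_cpcs: int = 13
    n_referrals: int = 1000
    labeled_fraction: float = 0.097
    imbalance: str = "table3"  # table3 | uniform
    class_weights: dict[str, dict[str, float]] | None = None  # group -> id -> w
    adult_fraction: float = 0.67
    terms_per_referral: tuple[int, int] = (6, 12)
    signal_fraction: float = 0.8
    typo_rate: float = 0.05
    historical_noise: float = 0.3
    condition_terms: int = 3
    terms_per_category_unit: int = 3
    background_vocab_size: int = 60

    def __post_init__(self) -> None:
        for name in ("labeled_fraction", "signal_fraction", "typo_rate",
                     "historical_noise", "adult_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_referrals < 0:
            raise ValueError("n_referrals must be >= 0")
        if self.n_adult_cpcs < 2 or self.n_paediatric_cpcs < 2:
            raise ValueError("need at least 2 CPCs per age group")


def _make_word(rng: np.random.Generator, syllables: int) -> str:
    parts = []
    for _ in range(syllables):
        parts.append(rng.choice(list(_CONSONANTS)))
        parts.append(rng.choice(list(_VOWELS_MID)))
    word = "".join(parts[:-1])  # drop last vowel, re-add a safe ending
    word += rng.choice(list(_VOWELS_END)) + rng.choice(list(_SAFE_FINALS))
    return word


def _word_pool(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct pseudo-words that are Porter-stemmer fixed points."""
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < n:
        word = _make_word(rng, int(rng.integers(2, 4)))
        if word in seen or word in DEFAULT_STOPWORDS:
            continue
        if porter_stem(word) != word:
            continue
        seen.add(word)
        pool.append(word)
    return pool


def _variant(word: str, rng: np.random.Generator) -> str:
    # morphological look-alike sharing the word's prefix
    return word + rng.choice(["ag", "um", "ik", "op"])


def generate_catalog(
    config: GeneratorConfig,
) -> tuple[CpcCatalog, dict[tuple[str, str], dict[int, list[str]]]]:
    """Build a synthetic catalog plus the ground-truth vocabulary map
    (age_group, cpc_id) -> category -> unit terms. Deterministic per seed.

    Each condition gets a core vocabulary disjoint from every other
    condition's: a set of condition terms shared by all three category units
    (referrals for one condition share vocabulary whatever their urgency)
    plus per-category qualifier terms that discriminate urgency. The
    keyword unit for category c is condition terms + qualifiers(c).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_cond = config.condition_terms
    n_qual = config.terms_per_category_unit
    per_cpc = n_cond + n_qual * len(CATEGORIES)
    n_total = (config.n_adult_cpcs + config.n_paediatric_cpcs) * per_cpc
    pool = _word_pool(rng, n_total + config.background_vocab_size + 20)
    background = pool[n_total : n_total + config.background_vocab_size]
    fillers = pool[n_total + config.background_vocab_size :]
    entries: list[CpcDefinition] = []
    vocab_map: dict[tuple[str, str], dict[int, list[str]]] = {}
    cursor = 0
    for group, count, freq_table in (
        ("adult", config.n_adult_cpcs, ADULT_CPC_FREQUENCIES),
        ("paediatric", config.n_paediatric_cpcs, PAEDIATRIC_CPC_FREQUENCIES),
    ):
        if count == len(freq_table):
            names = list(freq_table)
        else:
            names = [f"synthetic condition {group} {i + 1}" for i in range(count)]
        for name in names:
            core = pool[cursor : cursor + per_cpc]
            cursor += per_cpc
            condition_terms = core[:n_cond]
            units: dict[int, list[str]] = {}
            for j, cat in enumerate(CATEGORIES):
                lo = n_cond + j * n_qual
                units[cat] = list(condition_terms) + core[lo : lo + n_qual]
            keywords = {c: list(t) for c, t in units.items()}
            medical_terms = {
                c: list(t) + [_variant(t[-1], rng)] for c, t in units.items()
            }
            criteria_words = {
                c: list(medical_terms[c])
                + list(rng.choice(fillers, size=2, replace=False))
                for c in CATEGORIES
            }
            fixed = (
                FIXED_CATEGORY_CONDITIONS.get(name) if group == "adult" else None
            )
            entries.append(
                CpcDefinition(
                    cpc_id=slugify(name),
                    age_group=group,
                    condition_name=name,
                    representations={
                        "keywords": keywords,
                        "medical_terms": medical_terms,
                        "criteria_words": criteria_words,
                    },
                    fixed_category=fixed,
                )
            )
            vocab_map[(group, slugify(name))] = units
    return CpcCatalog(entries), {"background": background, **vocab_map}


def imbalance_profile(
    name: str,
    catalog: CpcCatalog,
    age_group: str,
    custom: dict[str, float] | None = None,
) -> dict[str, float]:
    """Class weights per cpc_id for one age group.

    ``table3`` reproduces the published labeled-set frequencies (normalized;
    zero-frequency conditions keep weight 0 but stay in the catalog),
    ``uniform`` spreads mass evenly, ``custom`` validates a user map.
    """
    entries = catalog.for_age_group(age_group)
    if name == "uniform":
        return {e.cpc_id: 1.0 / len(entries) for e in entries}
    if name == "custom":
        if custom is None:
            raise ValueError("custom profile requires a weight map")
        if abs(sum(custom.values()) - 1.0) > 1e-9:
            raise ValueError("custom class weights must sum to 1")
        return dict(custom)
    if name == "table3":
        table = (
            ADULT_CPC_FREQUENCIES if age_group == "adult"
            else PAEDIATRIC_CPC_FREQUENCIES
        )
        freq_by_id = {slugify(k): v for k, v in table.items()}
        missing = [e.cpc_id for e in entries if e.cpc_id not in freq_by_id]
        if missing:
            raise ValueError(
                f"table3 profile needs the default condition names; no "
                f"frequencies for {missing}"
            )
        total = sum(freq_by_id[e.cpc_id] for e in entries)
        return {e.cpc_id: freq_by_id[e.cpc_id] / total for e in entries}
    raise ValueError(f"unknown imbalance profile {name!r}")


def _edit_once(word: str, rng: np.random.Generator) -> str:
    """One uniformly chosen single-character substitution/insertion/deletion;
    guaranteed to differ from the input."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    while True:
        op = rng.choice(["sub", "ins", "del"] if len(word) > 1 else ["sub", "ins"])
        pos = int(rng.integers(0, len(word)))
        if op == "sub":
            out = word[:pos] + str(rng.choice(list(letters))) + word[pos + 1 :]
        elif op == "ins":
            pos = int(rng.integers(0, len(word) + 1))
            out = word[:pos] + str(rng.choice(list(letters))) + word[pos:]
        else:
            out = word[:pos] + word[pos + 1 :]
        if out != word and out:
            return out


def inject_typo(word: str, rng: np.random.Generator, rate: float = 1.0) -> str:
    """Corrupt a word with single-character edits.

    ``rate`` is the per-character probability of an edit, so a word of
    length L receives Binomial(L, rate) single-character substitutions,
    insertions or deletions — emulating both isolated typos (low rate) and
    heavier spelling variants such as run-together compounds (high rate).
    Any word that receives at least one edit is guaranteed to differ from
    the original.
    """
    n_edits = int(rng.binomial(len(word), rate)) if rate < 1.0 else len(word)
    if n_edits == 0:
        return word
    out = word
    for _ in range(n_edits):
        out = _edit_once(out, rng)
    while out == word:
        out = _edit_once(out, rng)
    return out


def _dates_for_group(
    group: str, rng: np.random.Generator
) -> tuple[dt.date, dt.date]:
    submitted = dt.date(2019, 1, 1) + dt.timedelta(days=int(rng.integers(0, 1277)))
    if group == "adult":
        age_days = int(rng.integers(17, 90)) * 366 + int(rng.integers(0, 300))
    else:
        age_days = int(rng.integers(0, 15)) * 365 + int(rng.integers(0, 300))
    return submitted - dt.timedelta(days=age_days), submitted


def generate_referrals(
    catalog: CpcCatalog,
    vocab_map: dict,
    config: GeneratorConfig,
) -> tuple[list[Referral], pd.DataFrame]:
    """Sample a referral corpus; returns the referrals and the ground truth
    (referral_id, age_group, true_cpc, true_category)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    background = vocab_map["background"]
    weights = {}
    for group in ("adult", "paediatric"):
        if config.class_weights and group in config.class_weights:
            weights[group] = imbalance_profile(
                "custom", catalog, group, config.class_weights[group]
            )
        else:
            weights[group] = imbalance_profile(config.imbalance, catalog, group)
    referrals: list[Referral] = []
    truth_rows = []
    lo, hi = config.terms_per_referral
    for i in range(config.n_referrals):
        rid = f"R{i:06d}"
        group = "adult" if rng.random() < config.adult_fraction else "paediatric"
        ids = list(weights[group])
        cpc_id = str(rng.choice(ids, p=[weights[group][c] for c in ids]))
        entry = catalog.get(cpc_id, group)
        units = vocab_map[(group, cpc_id)]
        if entry.fixed_category is not None:
            category = entry.fixed_category
        else:
            category = int(rng.choice(CATEGORIES))
        unit = units[category]
        n_terms = int(rng.integers(lo, hi + 1))
        n_signal = max(1, round(config.signal_fraction * n_terms)) \
            if config.signal_fraction > 0 else 0
        n_signal = min(n_signal, n_terms)
        if n_signal <= len(unit):
            signal = list(rng.choice(unit, size=n_signal, replace=False))
        else:
            signal = list(unit) + list(
                rng.choice(unit, size=n_signal - len(unit), replace=True)
            )
        # referral phrasing follows the criteria wording order
        unit_pos = {t: p for p, t in enumerate(unit)}
        signal.sort(key=unit_pos.__getitem__)
        signal = [inject_typo(w, rng, config.typo_rate) for w in signal]
        terms = list(signal)
        for w in rng.choice(background, size=n_terms - n_signal, replace=True):
            terms.insert(int(rng.integers(0, len(terms) + 1)), str(w))
        dob, submitted = _dates_for_group(group, rng)
        labeled = rng.random() < config.labeled_fraction
        if rng.random() < config.historical_noise:
            others = [c for c in CATEGORIES if c != category]
            historical = int(rng.choice(others))
        else:
            historical = category
        referrals.append(
            Referral(
                referral_id=rid,
                raw_text=", ".join(terms) + ".",
                entities=[
                    EntityRecord(t, "Medical_Condition", "DX_Name", 1.0)
                    for t in terms
                ],
                medical_terms=list(terms),
                date_of_birth=dob,
                submission_date=submitted,
                raw_cpc_label=entry.condition_name if labeled else None,
                historical_category=historical,
                lodgment="GPSR" if labeled else str(
                    rng.choice(["email", "fax", "GPSR", "manual"])
                ),
            )
        )
        truth_rows.append(
            {
                "referral_id": rid,
                "age_group": group,
                "true_cpc": cpc_id,
                "true_category": category,
            }
        )
    return referrals, pd.DataFrame(truth_rows)


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[CpcCatalog, dict, list[Referral], pd.DataFrame]:
    catalog, vocab_map = generate_catalog(config)
    referrals, truth = generate_referrals(catalog, vocab_map, config)
    return catalog, vocab_map, referrals, truth


def write_corpus(
    out_dir,
    catalog: CpcCatalog,
    referrals: list[Referral],
    truth: pd.DataFrame,
) -> dict[str, Path]:
    """Write catalog JSON, referral CSV, entity JSON and ground-truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": out / "catalog.json",
        "referrals": out / "referrals.csv",
        "entities": out / "entities.json",
        "truth": out / "truth.csv",
    }
    catalog.save(paths["catalog"])
    pd.DataFrame(
        [
            {
                "referral_id": r.referral_id,
                "text": r.raw_text,
                "dob": r.date_of_birth.isoformat(),
                "submitted": r.submission_date.isoformat(),
                "cpc_label": r.raw_cpc_label,
                "category": r.historical_category,
                "lodgment": r.lodgment,
            }
            for r in referrals
        ]
    ).to_csv(paths["referrals"], index=False)
    entities = {
        r.referral_id: {
            "Entities": [
                {"Text": e.text, "Category": e.category, "Type": e.type,
                 "Score": e.score}
                for e in r.entities
            ]
        }
        for r in referrals
    }
    with open(paths["entities"], "w") as fh:
        json.dump(entities, fh)
    truth.to_csv(paths["truth"], index=False)
    return paths
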