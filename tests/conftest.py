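import datetime as dt

import pytest

from cpctriage.catalog import CpcCatalog, CpcDefinition
from cpctriage.preprocess import EntityRecord, Referral
from cpctriage.synth import GeneratorConfig, generate_corpus


def _units(*cats):
    return {i + 1: list(tokens) for i, tokens in enumerate(cats)}


@pytest.fixture
def toy_catalog() -> CpcCatalog:
    """Two adult + two paediatric conditions with tiny disjoint vocabularies."""
    return CpcCatalog(
        [
            CpcDefinition(
                cpc_id="hearing-loss",
                age_group="adult",
                condition_name="hearing loss",
                representations={
                    "keywords": _units(
                        ["hear", "loss", "sudden"],
                        ["hear", "loss", "gradual"],
                        ["hear", "loss", "mild"],
                    ),
                    "medical_terms": _units(
                        ["hear", "loss", "deaf"],
                        ["hear", "loss", "presbycusi"],
                        ["hear", "loss", "wax"],
                    ),
                },
            ),
            CpcDefinition(
                cpc_id="tinnitus",
                age_group="adult",
                condition_name="tinnitus",
                representations={
                    "keywords": _units(
                        ["tinnitu", "puls", "unilater"],
                        ["tinnitu", "persist"],
                        ["tinnitu", "intermitt"],
                    ),
                },
            ),
            CpcDefinition(
                cpc_id="neck-mass",
                age_group="adult",
                condition_name="head and neck mass",
                fixed_category=1,
                representations={
                    "keywords": _units(["neck", "mass"], ["neck", "lump"], []),
                },
            ),
            CpcDefinition(
                cpc_id="stridor",
                age_group="paediatric",
                condition_name="stridor",
                representations={
                    "keywords": _units(
                        ["stridor", "rest"], ["stridor", "feed"], ["stridor"]
                    ),
                },
            ),
            CpcDefinition(
                cpc_id="glue-ear",
                age_group="paediatric",
                condition_name="otitis media with effusion",
                representations={
                    "keywords": _units(
                        ["glue", "ear", "speech"], ["glue", "ear"], ["glue"]
                    ),
                },
            ),
        ]
    )


@pytest.fixture
def adult_referral() -> Referral:
    return Referral(
        referral_id="A1",
        raw_text="Sudden hearing loss for 3 months.",
        entities=[
            EntityRecord("hearing loss", "Medical_Condition", "DX_Name", 0.99),
            EntityRecord("sudden", "Medical_Condition", "DX_Name", 0.8),
        ],
        date_of_birth=dt.date(1980, 5, 1),
        submission_date=dt.date(2021, 3, 2),
        raw_cpc_label="Hearing Loss",
        historical_category=1,
    )


@pytest.fixture(scope="session")
def noisefree_corpus():
    """Corpus where every generator truth is recoverable: full signal, no
    typos, historical categories equal to the CPC-implied categories."""
    config = GeneratorConfig(
        seed=7,
        n_referrals=500,
        signal_fraction=1.0,
        typo_rate=0.0,
        historical_noise=0.0,
    )
    catalog, vocab_map, referrals, truth = generate_corpus(config)
    return config, catalog, vocab_map, referrals, truth


@pytest.fixture(scope="session")
def default_corpus():
    """Corpus at the default study conditions (imbalanced classes, 9.7%
    labeled, background noise, typos, historical disagreement)."""
    config = GeneratorConfig(seed=3, n_referrals=800)
    catalog, vocab_map, referrals, truth = generate_corpus(config)
    return config, catalog, vocab_map, referrals, truth
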