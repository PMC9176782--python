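from __future__ import annotations

import datetime as dt
import random

import pytest
from hypothesis import settings

import casefinder as cf
from casefinder.synthetic_registry import (
    GENERIC_M8_CODE,
    LUNG_T,
    MISCODE,
    NSCLC_SPECIFIC_CODES,
    OTHER_SITE_TS,
    RESP_NOS_T,
    UPPER_AIRWAY_TS,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ruleset() -> cf.RuleSet:
    return cf.default_ruleset()


@pytest.fixture(scope="session")
def small_dataset() -> cf.SyntheticDataset:
    """A 2,000-patient synthetic world shared by the faster tests."""
    return cf.generate(cf.SyntheticParams.paperlike(n_patients=2000, seed=7))


@pytest.fixture(scope="session")
def paperlike_50k() -> cf.SyntheticDataset:
    """The full-size default synthetic world (parameter-recovery scale)."""
    return cf.generate(cf.SyntheticParams.paperlike())


_FUZZ_CODES_M = [
    *NSCLC_SPECIFIC_CODES, "M-82463", GENERIC_M8_CODE, MISCODE,
    "M-85003", "M-80000", "M-89803", "M-97323", "M-00100",
]
_FUZZ_CODES_T = [
    LUNG_T, RESP_NOS_T, *UPPER_AIRWAY_TS, *OTHER_SITE_TS,
    "T-26000", "T-29990", "T-2", "T-30000",
]
_FUZZ_WORDS = [
    "adenocarcinoma", "ADENOCARCINOMA", "adenocarcinòma", "squamocellulare",
    "microcitoma", "non", "non microcitoma", "a grandi cellule", "grandi",
    "cellule", "polmone", "polmonare", "POLMONE", "bronchiale", "bronco",
    "carcinoma", "mammella", "laringe", "metastasi", "lesione", "benigna",
    "città", "perché", "nodulo", "sinistro", "microcitoma polmonare",
]


def make_fuzz_record(rng: random.Random, index: int) -> cf.PathologyRecord:
    """Adversarial random record: decoy codes and keyword fragments."""
    morph = rng.sample(_FUZZ_CODES_M, rng.randint(0, 3))
    topo = rng.sample(_FUZZ_CODES_T, rng.randint(0, 3))
    text = " ".join(rng.choice(_FUZZ_WORDS) for _ in range(rng.randint(0, 8)))
    return cf.PathologyRecord(
        record_id=f"F{index:05d}",
        patient_id=f"PF{index:05d}",
        sample_date=dt.date(2010, 1, 1) + dt.timedelta(days=rng.randint(0, 2000)),
        morphology_codes=morph,
        topography_codes=topo,
        diagnosis_text=text,
    )


@pytest.fixture()
def fuzz_records():
    def _make(n: int, seed: int = 20090101) -> list[cf.PathologyRecord]:
        rng = random.Random(seed)
        return [make_fuzz_record(rng, i) for i in range(n)]

    return _make
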