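"""Synthetic pathology-registry simulator with known ground truth.

No real registry extract can be shipped, so every downstream module is
exercised against a simulated region: each synthetic patient carries a true
condition class (primary NSCLC, neuroendocrine lung tumour, upper-airway
cancer, cancer of another site, lung metastasis of another primary, or a
benign lesion), and captured patients emit pathology records whose SNOMED
codes and Italian diagnosis text are drawn from a small class-conditional
emission model:

* a true NSCLC case receives a specific NSCLC morphology code with
  probability ``coding_fidelity``; otherwise either a generic ``M-8*`` code
  whose diagnosis text may carry a histology keyword (adenocarcinoma,
  squamous, large-cell, non-small-cell), or an outright miscode;
* topography is a specific lung code, a respiratory-NOS code, or absent
  (lung then findable only through ``POLM*``/``BRONCH*`` keywords);
* non-lung reports occasionally mention the lung in free text (suspected
  pulmonary metastases), creating realistic false positives;
* registry capture of a true case's report varies by calendar year
  (non-decreasing by default, emulating a young registry whose completeness
  grows), and hospital-treated patients are captured at a higher rate.

Because the emission model is a finite product of independent choices,
``expected_validity`` computes the exact flag probability of every
condition class under every algorithm version by enumerating the outcome
space, and from those the closed-form expected PPV and per-year expected
sensitivity — the yardstick for parameter-recovery tests.

The generator also simulates the manual-review layer: two independent
raters who deviate from the per-item truth with probability
``rater_error`` (softening to "maybe" with probability ``maybe_prob``),
plus an error-free referee, so adjudication, confirmation and kappa can be
exercised end to end.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .phenotype_engine import RuleSet, _RecordView, _eval, default_ruleset
from .registry_model import (
    PathologyRecord,
    ResidencyIndex,
    ReviewForm,
    TreatmentRecord,
    write_persons,
    write_population,
    write_registry,
    write_reviews,
    write_treatments,
)

__all__ = [
    "CLASSES",
    "SyntheticParams",
    "SyntheticDataset",
    "EmissionOutcome",
    "ExpectedValidity",
    "emission_distribution",
    "outcome_record",
    "generate",
    "expected_validity",
]

CLASSES = (
    "primary_NSCLC",
    "neuroendocrine_lung",
    "upper_airway_cancer",
    "other_site_cancer",
    "lung_metastasis",
    "benign",
)

# Specific NSCLC morphology codes of the inclusion list (neuroendocrine
# M-82463 deliberately excluded: it is carried by its own class).
NSCLC_SPECIFIC_CODES = (
    "M-81403", "M-80703", "M-85603", "M-83233", "M-85503",
    "M-84303", "M-82503", "M-80033", "M-80123", "M-80463",
)
GENERIC_M8_CODE = "M-80103"   # carcinoma NOS: M-8* but not on the specific list
MISCODE = "M-95903"           # lymphoma-range decoy, outside M-8*
LUNG_T = "T-28000"
RESP_NOS_T = "T-20000"
UPPER_AIRWAY_TS = ("T-21000", "T-22000", "T-23000", "T-24000", "T-25000")
OTHER_SITE_TS = ("T-55000", "T-67000", "T-71000")

_BASE_TEXT = {
    "primary_NSCLC": "quadro istologico di neoplasia maligna",
    "neuroendocrine_lung": "carcinoma neuroendocrino del polmone",
    "upper_airway_cancer": "carcinoma squamocellulare della laringe",
    "other_site_cancer": "adenocarcinoma del tratto gastroenterico",
    "lung_metastasis": "metastasi polmonare di adenocarcinoma di verosimile origine colica",
    "benign": "parenchima polmonare con flogosi cronica, assenza di atipie",
}
# Each phrase carries exactly one histology keyword and no lung keyword.
MORPH_KW_PHRASES = (
    "aspetti di adenocarcinoma infiltrante",
    "differenziazione squamocellulare",
    "carcinoma a grandi cellule",
    "carcinoma non microcitoma",
)
# Each phrase carries a lung keyword and no histology keyword.
LUNG_KW_PHRASES = (
    "localizzazione polmonare",
    "prelievo bioptico bronchiale",
)
_NSCLC_DRUGS = ("cisplatino", "pemetrexed", "gemcitabina", "nivolumab", "docetaxel")
_OTHER_DRUGS = ("oxaliplatino", "fluorouracile", "trastuzumab")

# Per-item review truth (malignancy, lung site, NSCLC morphology, primary
# origin) by true class; primary-origin of a true NSCLC softens to "maybe"
# with origin_maybe_prob at generation time.
_REVIEW_TRUTH = {
    "primary_NSCLC": ("yes", "yes", "yes", "yes"),
    "neuroendocrine_lung": ("yes", "yes", "no", "yes"),
    "upper_airway_cancer": ("yes", "no", "yes", "yes"),
    "other_site_cancer": ("yes", "no", "yes", "yes"),
    "lung_metastasis": ("yes", "yes", "yes", "no"),
    "benign": ("no", "yes", "no", "no"),
}


@dataclass(frozen=True)
class SyntheticParams:
    """Generator configuration; defaults mirror the shipped ``paperlike.params``."""

    n_patients: int = 50_000
    years: tuple[int, int] = (2009, 2017)
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "primary_NSCLC": 0.25,
            "neuroendocrine_lung": 0.03,
            "upper_airway_cancer": 0.05,
            "other_site_cancer": 0.42,
            "lung_metastasis": 0.012,
            "benign": 0.238,
        }
    )
    coding_fidelity: float = 0.85
    generic_text_frac: float = 0.7
    keyword_emission: float = 0.8
    topography_fidelity: float = 0.92
    resp_nos_prob: float = 0.03
    decoy_lung_text_prob: float = 0.0165
    capture_by_year: Mapping[int, float] | None = None
    treatment_prob: float = 0.10
    treated_capture: float = 0.85
    other_treatment_prob: float = 0.05
    resident_prob: float = 0.87
    extra_record_prob: float = 0.2
    rater_error: float = 0.05
    maybe_prob: float = 0.5
    origin_maybe_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.years[0] > self.years[1]:
            raise ValueError("years must satisfy start <= end")
        if set(self.class_mix) != set(CLASSES):
            raise ValueError(f"class_mix must cover exactly {CLASSES}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        probs = [
            self.coding_fidelity, self.generic_text_frac, self.keyword_emission,
            self.topography_fidelity, self.resp_nos_prob, self.decoy_lung_text_prob,
            self.treatment_prob, self.treated_capture, self.other_treatment_prob,
            self.resident_prob, self.extra_record_prob, self.rater_error,
            self.maybe_prob, self.origin_maybe_prob, *self.class_mix.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.topography_fidelity + self.resp_nos_prob > 1.0:
            raise ValueError("topography_fidelity + resp_nos_prob must not exceed 1")
        capture = self.capture
        missing = [y for y in self.year_range if y not in capture]
        if missing:
            raise ValueError(f"capture_by_year missing year(s) {missing}")
        if any(not 0.0 <= capture[y] <= 1.0 for y in self.year_range):
            raise ValueError("capture probabilities must lie in [0, 1]")

    @property
    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)

    @property
    def capture(self) -> dict[int, float]:
        """Capture probabilities; default ramps linearly 0.20 -> 0.70."""
        if self.capture_by_year is not None:
            return {int(y): float(p) for y, p in self.capture_by_year.items()}
        years = list(self.year_range)
        if len(years) == 1:
            return {years[0]: 0.45}
        return {
            y: 0.20 + (0.70 - 0.20) * i / (len(years) - 1) for i, y in enumerate(years)
        }

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SyntheticParams":
        path = Path(source)
        doc = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        return cls.from_mapping(doc)

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "SyntheticParams":
        kwargs = dict(doc)
        if "years" in kwargs:
            kwargs["years"] = tuple(int(y) for y in kwargs["years"])
        if kwargs.get("capture_by_year") is not None:
            kwargs["capture_by_year"] = {
                int(y): float(p) for y, p in kwargs["capture_by_year"].items()
            }
        return cls(**kwargs)

    @classmethod
    def paperlike(cls, **overrides) -> "SyntheticParams":
        """The shipped default configuration, with optional field overrides."""
        text = resources.files("casefinder.data").joinpath("paperlike.params").read_text("utf-8")
        params = cls.from_mapping(yaml.safe_load(text))
        return replace(params, **overrides) if overrides else params


@dataclass(frozen=True)
class EmissionOutcome:
    """One atom of a class's finite emission space.

    ``morph_pool``/``topo_pool`` list flag-equivalent codes of which the
    generator samples one (empty pool = no code on that axis).
    """

    prob: float
    morph_pool: tuple[str, ...]
    topo_pool: tuple[str, ...]
    morph_kw: bool
    lung_kw: bool
    base: str


def emission_distribution(true_class: str, params: SyntheticParams) -> list[EmissionOutcome]:
    """The exact record-emission distribution of one condition class."""
    if true_class == "primary_NSCLC":
        cf, gf, ke = params.coding_fidelity, params.generic_text_frac, params.keyword_emission
        tf, nos = params.topography_fidelity, params.resp_nos_prob
        morph_branches = [
            (cf, NSCLC_SPECIFIC_CODES),
            ((1 - cf) * gf, (GENERIC_M8_CODE,)),
            ((1 - cf) * (1 - gf), (MISCODE,)),
        ]
        topo_branches = [(tf, (LUNG_T,)), (nos, (RESP_NOS_T,)), (1 - tf - nos, ())]
        outcomes = []
        for p_m, m_pool in morph_branches:
            for p_mk, mkw in ((ke, True), (1 - ke, False)):
                for p_t, t_pool in topo_branches:
                    for p_lk, lkw in ((ke, True), (1 - ke, False)):
                        prob = p_m * p_mk * p_t * p_lk
                        if prob > 0:
                            outcomes.append(
                                EmissionOutcome(prob, m_pool, t_pool, mkw, lkw, true_class)
                            )
        return outcomes
    if true_class == "neuroendocrine_lung":
        return [EmissionOutcome(1.0, ("M-82463",), (LUNG_T,), False, False, true_class)]
    if true_class == "upper_airway_cancer":
        return [EmissionOutcome(1.0, ("M-80703",), UPPER_AIRWAY_TS, False, False, true_class)]
    if true_class == "other_site_cancer":
        dk = params.decoy_lung_text_prob
        out = [EmissionOutcome(1 - dk, ("M-81403",), OTHER_SITE_TS, False, False, true_class)]
        if dk > 0:
            out.append(EmissionOutcome(dk, ("M-81403",), OTHER_SITE_TS, False, True, true_class))
        return out
    if true_class == "lung_metastasis":
        return [EmissionOutcome(1.0, ("M-81403",), (LUNG_T,), False, False, true_class)]
    if true_class == "benign":
        return [EmissionOutcome(1.0, (), (LUNG_T,), False, False, true_class)]
    raise ValueError(f"unknown class {true_class!r}")


def _compose_text(outcome: EmissionOutcome, morph_phrase: str, lung_phrase: str) -> str:
    parts = [_BASE_TEXT[outcome.base]]
    if outcome.morph_kw:
        parts.append(morph_phrase)
    if outcome.lung_kw:
        parts.append(lung_phrase)
    return ", ".join(parts)


def outcome_record(outcome: EmissionOutcome) -> PathologyRecord:
    """Representative record of an outcome (first pool member, first phrases)."""
    return PathologyRecord(
        record_id="enum",
        patient_id="enum",
        sample_date=_dt.date(2000, 1, 1),
        morphology_codes=list(outcome.morph_pool[:1]),
        topography_codes=list(outcome.topo_pool[:1]),
        diagnosis_text=_compose_text(outcome, MORPH_KW_PHRASES[0], LUNG_KW_PHRASES[0]),
    )


@dataclass
class SyntheticDataset:
    """Generated registry world plus per-record and per-patient ground truth."""

    params: SyntheticParams
    records: list[PathologyRecord]
    persons: dict[str, bool]
    residency: ResidencyIndex
    treatments: list[TreatmentRecord]
    reviews: list[ReviewForm]
    truth_class: dict[str, str]            # record_id -> true class
    patient_truth: pd.DataFrame            # index patient_id: true_class, year, resident,
                                           # treated, captured, is_true_case

    @property
    def truth_case(self) -> dict[str, bool]:
        return self.patient_truth["is_true_case"].to_dict()

    @property
    def window(self) -> tuple[_dt.date, _dt.date]:
        y0, y1 = self.params.years
        return _dt.date(y0, 1, 1), _dt.date(y1, 12, 31)

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_registry(self.records, out / "records.csv")
        write_persons(self.persons, out / "persons.csv")
        write_population(self.residency.population_by_year, out / "population.csv")
        write_treatments(self.treatments, out / "treatments.csv")
        write_reviews(self.reviews, out / "reviews.csv")
        truth = pd.DataFrame(
            [
                {"record_id": rid, "true_class": cls}
                for rid, cls in self.truth_class.items()
            ]
        )
        truth.to_csv(out / "truth.csv", index=False)
        self.patient_truth.to_csv(out / "patient_truth.csv", index_label="patient_id")


def _sample_outcome(
    rng: np.random.Generator, outcomes: Sequence[EmissionOutcome], cum: np.ndarray
) -> EmissionOutcome:
    return outcomes[int(np.searchsorted(cum, rng.random(), side="right"))]


def _rate_item(rng: np.random.Generator, truth: str, params: SyntheticParams) -> str:
    if rng.random() >= params.rater_error:
        return truth
    if truth == "maybe":
        return "yes" if rng.random() < 0.5 else "no"
    if rng.random() < params.maybe_prob:
        return "maybe"
    return "no" if truth == "yes" else "yes"


def generate(params: SyntheticParams, ruleset: RuleSet | None = None) -> SyntheticDataset:
    """Generate a full synthetic registry world, reproducibly from the seed.

    Three independent pseudo-random streams (records, treatments, raters)
    derive from the master seed, so adding raters or treatments never
    perturbs record generation.
    """
    ruleset = ruleset or default_ruleset()
    first_version = ruleset.algorithms["first_version"]
    ss_records, ss_treat, ss_rate = np.random.SeedSequence(params.seed).spawn(3)
    rec_rng = np.random.default_rng(ss_records)
    treat_rng = np.random.default_rng(ss_treat)
    rate_rng = np.random.default_rng(ss_rate)

    n = params.n_patients
    mix = np.array([params.class_mix[c] for c in CLASSES])
    capture = params.capture
    y0, y1 = params.years
    window_end = _dt.date(y1, 12, 31)

    cls_idx = rec_rng.choice(len(CLASSES), size=n, p=mix) if n else np.empty(0, dtype=int)
    resident = rec_rng.random(n) < params.resident_prob
    years = rec_rng.integers(y0, y1 + 1, size=n) if n else np.empty(0, dtype=int)
    u_treat = rec_rng.random(n)
    u_capture = rec_rng.random(n)

    dists = {c: emission_distribution(c, params) for c in CLASSES}
    cums = {c: np.cumsum([o.prob for o in dists[c]]) for c in CLASSES}

    records: list[PathologyRecord] = []
    truth_class: dict[str, str] = {}
    persons: dict[str, bool] = {}
    patient_rows: list[dict] = []
    flagged_first: list[tuple[str, str]] = []  # (record_id, true class) for review layer
    rid_counter = 0

    for p in range(n):
        pid = f"P{p:06d}"
        cls = CLASSES[cls_idx[p]]
        year = int(years[p])
        treated = cls == "primary_NSCLC" and u_treat[p] < params.treatment_prob
        p_cap = params.treated_capture if treated else capture[year]
        captured = u_capture[p] < p_cap
        persons[pid] = bool(resident[p])
        patient_rows.append(
            {
                "patient_id": pid,
                "true_class": cls,
                "year": year,
                "resident": bool(resident[p]),
                "treated": treated,
                "captured": captured,
                "is_true_case": cls == "primary_NSCLC",
            }
        )
        if not captured:
            continue
        outcome = _sample_outcome(rec_rng, dists[cls], cums[cls])
        morph = [str(rec_rng.choice(outcome.morph_pool))] if outcome.morph_pool else []
        topo = [str(rec_rng.choice(outcome.topo_pool))] if outcome.topo_pool else []
        text = _compose_text(
            outcome,
            str(rec_rng.choice(MORPH_KW_PHRASES)),
            str(rec_rng.choice(LUNG_KW_PHRASES)),
        )
        date = _dt.date(year, 1, 1) + _dt.timedelta(days=int(rec_rng.integers(0, 365)))
        n_records = 2 if rec_rng.random() < params.extra_record_prob else 1
        for k in range(n_records):
            rid = f"R{rid_counter:07d}"
            rid_counter += 1
            rec_date = date
            if k == 1:
                rec_date = min(date + _dt.timedelta(days=int(rec_rng.integers(10, 200))),
                               window_end)
            record = PathologyRecord(
                record_id=rid,
                patient_id=pid,
                sample_date=rec_date,
                morphology_codes=list(morph),
                topography_codes=list(topo),
                diagnosis_text=text,
                macroscopy_text="frammento di tessuto inviato in toto",
                microscopy_text="esame istologico su inclusione in paraffina",
                clinical_info_text="accertamento diagnostico",
                sent_material_text="biopsia",
            )
            records.append(record)
            truth_class[rid] = cls
            if ruleset.evaluate(record, "first_version"):
                flagged_first.append((rid, cls))

    # Hospital-pharmacy table: NSCLC-indicated administrations for treated
    # true cases, plus background OTHER-indicated administrations.
    treatments: list[TreatmentRecord] = []
    for row in patient_rows:
        if row["treated"]:
            for _ in range(int(treat_rng.integers(1, 4))):
                day = int(treat_rng.integers(30, 330))
                treatments.append(
                    TreatmentRecord(
                        patient_id=row["patient_id"],
                        administration_date=_dt.date(row["year"], 1, 1) + _dt.timedelta(days=day),
                        drug_name=str(treat_rng.choice(_NSCLC_DRUGS)),
                        indication="NSCLC",
                    )
                )
        elif row["true_class"] == "other_site_cancer":
            if treat_rng.random() < params.other_treatment_prob:
                day = int(treat_rng.integers(30, 330))
                treatments.append(
                    TreatmentRecord(
                        patient_id=row["patient_id"],
                        administration_date=_dt.date(row["year"], 1, 1) + _dt.timedelta(days=day),
                        drug_name=str(treat_rng.choice(_OTHER_DRUGS)),
                        indication="OTHER",
                    )
                )

    # Manual-review layer for every record the broadest version flags.
    reviews: list[ReviewForm] = []
    for rid, cls in flagged_first:
        truth_items = list(_REVIEW_TRUTH[cls])
        if cls == "primary_NSCLC" and rate_rng.random() < params.origin_maybe_prob:
            truth_items[3] = "maybe"
        for rater in ("rater_a", "rater_b"):
            levels = [_rate_item(rate_rng, t, params) for t in truth_items]
            reviews.append(ReviewForm(rid, rater, *levels))
        reviews.append(ReviewForm(rid, "referee", *truth_items))

    patient_truth = pd.DataFrame(
        patient_rows,
        columns=["patient_id", "true_class", "year", "resident", "treated",
                 "captured", "is_true_case"],
    ).set_index("patient_id")
    n_residents = int(patient_truth["resident"].sum()) if n else 0
    population = {year: max(n_residents, 1) for year in params.year_range}
    residency = ResidencyIndex(
        resident_ids=frozenset(pid for pid, res in persons.items() if res),
        population_by_year=population,
    )
    return SyntheticDataset(
        params=params,
        records=records,
        persons=persons,
        residency=residency,
        treatments=treatments,
        reviews=reviews,
        truth_class=truth_class,
        patient_truth=patient_truth,
    )


def _adjudicated_level_prob(truth: str, level: str, params: SyntheticParams) -> float:
    """Exact P(adjudicated item = level | item truth) under the rater model.

    Adjudication keeps the raters' value when they agree and falls back to
    the error-free referee (= truth) otherwise, so a wrong adjudicated level
    requires both raters to deviate to the same wrong level independently.
    """
    e, mp = params.rater_error, params.maybe_prob

    def p_rater(v: str) -> float:
        if v == truth:
            return 1.0 - e
        if truth == "maybe":
            return e / 2.0
        return e * mp if v == "maybe" else e * (1.0 - mp)

    if level == truth:
        return 1.0 - sum(p_rater(v) ** 2 for v in ("yes", "no", "maybe") if v != truth)
    return p_rater(level) ** 2


def expected_confirm_prob(params: SyntheticParams) -> dict[str, float]:
    """Exact P(adjudicated review confirms | true class), item-wise independent."""
    out: dict[str, float] = {}
    for cls in CLASSES:
        truths = [list(_REVIEW_TRUTH[cls])]
        weights = [1.0]
        if cls == "primary_NSCLC" and params.origin_maybe_prob > 0:
            omp = params.origin_maybe_prob
            truths = [list(_REVIEW_TRUTH[cls]), list(_REVIEW_TRUTH[cls])]
            truths[1][3] = "maybe"
            weights = [1.0 - omp, omp]
        prob = 0.0
        for w, items in zip(weights, truths):
            p = w
            for truth in items[:3]:
                p *= _adjudicated_level_prob(truth, "yes", params)
            p *= _adjudicated_level_prob(items[3], "yes", params) + _adjudicated_level_prob(
                items[3], "maybe", params
            )
            prob += p
        out[cls] = prob
    return out


@dataclass(frozen=True)
class ExpectedValidity:
    """Closed-form validity surface implied by the emission model."""

    flag_prob: Mapping[str, Mapping[str, float]]     # algorithm -> class -> P(flag | class)
    ppv: Mapping[str, float]                         # algorithm -> expected PPV
    se_by_year: Mapping[str, Mapping[int, float]]    # algorithm -> year -> expected SE
    se_indicator: Mapping[str, float]                # algorithm -> expected SE indicator
    review_ppv: Mapping[str, float]                  # algorithm -> expected review-based PPV

    @property
    def expected_ppv(self) -> Mapping[str, float]:
        return self.ppv

    @property
    def expected_se_by_year(self) -> Mapping[str, Mapping[int, float]]:
        return self.se_by_year


def expected_validity(
    params: SyntheticParams, ruleset: RuleSet | None = None
) -> ExpectedValidity:
    """Exact expected PPV and per-year SE by enumeration of the emission space.

    Flag probabilities come from evaluating every emission outcome of every
    class under every algorithm version; capture (with the treated-patient
    boost) and the class mix then yield expected PPV = P(true NSCLC |
    flagged) and expected SE(year) = P(flagged | true NSCLC, year).
    Residency is independent of everything else and cancels.
    """
    ruleset = ruleset or default_ruleset()
    algs = list(ruleset.algorithms)
    flag_prob: dict[str, dict[str, float]] = {a: {} for a in algs}
    for cls in CLASSES:
        outcomes = emission_distribution(cls, params)
        views = [(o.prob, _RecordView(outcome_record(o))) for o in outcomes]
        for alg in algs:
            version = ruleset.algorithms[alg]
            flag_prob[alg][cls] = sum(
                prob for prob, view in views
                if _eval(version.expression, view, version.components)
            )

    capture = params.capture
    years = list(params.year_range)
    tp, tc = params.treatment_prob, params.treated_capture
    cap_primary = {y: tp * tc + (1 - tp) * capture[y] for y in years}
    mean_cap_primary = sum(cap_primary.values()) / len(years)
    mean_cap_other = sum(capture[y] for y in years) / len(years)

    confirm_prob = expected_confirm_prob(params)
    ppv: dict[str, float] = {}
    review_ppv: dict[str, float] = {}
    se_by_year: dict[str, dict[int, float]] = {}
    se_ind: dict[str, float] = {}
    for alg in algs:
        flagged_mass = 0.0
        confirm_mass = 0.0
        for cls in CLASSES:
            mean_cap = mean_cap_primary if cls == "primary_NSCLC" else mean_cap_other
            mass = params.class_mix[cls] * flag_prob[alg][cls] * mean_cap
            flagged_mass += mass
            confirm_mass += mass * confirm_prob[cls]
        primary_mass = (
            params.class_mix["primary_NSCLC"]
            * flag_prob[alg]["primary_NSCLC"]
            * mean_cap_primary
        )
        ppv[alg] = primary_mass / flagged_mass if flagged_mass > 0 else float("nan")
        review_ppv[alg] = confirm_mass / flagged_mass if flagged_mass > 0 else float("nan")
        se_by_year[alg] = {
            y: flag_prob[alg]["primary_NSCLC"] * cap_primary[y] for y in years
        }
        se_ind[alg] = tc * flag_prob[alg]["primary_NSCLC"]
    return ExpectedValidity(
        flag_prob=flag_prob, ppv=ppv, se_by_year=se_by_year, se_indicator=se_ind,
        review_ppv=review_ppv,
    )
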