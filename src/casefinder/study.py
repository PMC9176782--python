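"""End-to-end validation study over a registry world with review data.

Ties the other modules together the way a validation study is actually run:
build the patient cohort of each algorithm version, adjudicate the
double-rated review forms of the index records and derive PPV, compute the
treatment-based sensitivity indicator against the hospital-pharmacy table,
and — when ground truth is available (synthetic data) — the truth-based
sensitivity by calendar year.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .cohort_builder import CaseCohort, annual_case_counts, build_cohort
from .phenotype_engine import RuleSet, default_ruleset
from .registry_model import (
    PathologyRecord,
    REVIEW_ITEMS,
    ResidencyIndex,
    ReviewForm,
    TreatmentRecord,
)
from .validation import (
    KappaResult,
    ValidityEstimate,
    adjudicate,
    cohens_kappa,
    confirm_case,
    ppv,
    se_indicator,
)

__all__ = [
    "ReviewSummary",
    "adjudicated_forms",
    "review_ppv",
    "treatment_se_indicator",
    "interrater_kappa",
    "StudyResult",
    "run_study",
]

logger = logging.getLogger(__name__)


def adjudicated_forms(
    reviews: Iterable[ReviewForm],
    rater_a: str = "rater_a",
    rater_b: str = "rater_b",
    referee: str = "referee",
) -> dict[str, ReviewForm]:
    """Item-wise adjudicated form per record from two raters plus a referee."""
    by_record: dict[str, dict[str, ReviewForm]] = {}
    for form in reviews:
        by_record.setdefault(form.record_id, {})[form.rater_id] = form
    out: dict[str, ReviewForm] = {}
    for rid, forms in by_record.items():
        if rater_a in forms and rater_b in forms and referee in forms:
            out[rid] = adjudicate(forms[rater_a], forms[rater_b], forms[referee])
    return out


def review_ppv(cohort: CaseCohort, adjudicated: Mapping[str, ReviewForm]) -> ValidityEstimate:
    """PPV of a cohort against its adjudicated index-record reviews.

    Index records without a review are dropped with a logged count (in a
    real study they would be the non-linkable cases).
    """
    reviewed = [
        adjudicated[r.record_id] for r in cohort.cases.values() if r.record_id in adjudicated
    ]
    dropped = len(cohort) - len(reviewed)
    if dropped:
        logger.info("review_ppv: %d of %d index records lack reviews", dropped, len(cohort))
    if not reviewed:
        raise ValueError("no reviewed index records; cannot estimate PPV")
    return ppv(sum(confirm_case(f) for f in reviewed), len(reviewed))


def treatment_se_indicator(
    cohort: CaseCohort,
    treatments: Iterable[TreatmentRecord],
    residency: ResidencyIndex | None = None,
    indication: str = "NSCLC",
) -> ValidityEstimate:
    """Share of treated patients (by indication) the algorithm identified."""
    treated = {t.patient_id for t in treatments if t.indication == indication}
    if residency is not None:
        treated = {pid for pid in treated if residency.is_resident(pid)}
    if not treated:
        raise ValueError(f"no treated patients with indication {indication!r}")
    return se_indicator(len(treated & cohort.patient_ids()), len(treated))


def interrater_kappa(
    reviews: Iterable[ReviewForm], rater_a: str = "rater_a", rater_b: str = "rater_b"
) -> dict[str, KappaResult]:
    """Per-item Cohen's kappa over the records both raters assessed."""
    forms_a: dict[str, ReviewForm] = {}
    forms_b: dict[str, ReviewForm] = {}
    for form in reviews:
        if form.rater_id == rater_a:
            forms_a[form.record_id] = form
        elif form.rater_id == rater_b:
            forms_b[form.record_id] = form
    common = sorted(set(forms_a) & set(forms_b))
    only_one = len(set(forms_a) ^ set(forms_b))
    if only_one:
        logger.info("interrater_kappa: dropping %d singly-rated records", only_one)
    if not common:
        raise ValueError("no records rated by both raters")
    return {
        item: cohens_kappa(
            [getattr(forms_a[r], item) for r in common],
            [getattr(forms_b[r], item) for r in common],
        )
        for item in REVIEW_ITEMS
    }


@dataclass
class StudyResult:
    """Everything a validation study reports, per algorithm version."""

    cohorts: dict[str, CaseCohort]
    annual_counts: dict[str, dict[int, int]]
    ppv: dict[str, ValidityEstimate]
    se_indicator: dict[str, ValidityEstimate]
    kappa: dict[str, KappaResult]


def run_study(
    records: Iterable[PathologyRecord],
    reviews: Iterable[ReviewForm],
    treatments: Iterable[TreatmentRecord],
    residency: ResidencyIndex,
    window: tuple[_dt.date, _dt.date],
    ruleset: RuleSet | None = None,
) -> StudyResult:
    """Run the full validation study for every algorithm version."""
    ruleset = ruleset or default_ruleset()
    records = list(records)
    reviews = list(reviews)
    treatments = list(treatments)
    adjudicated = adjudicated_forms(reviews)
    cohorts: dict[str, CaseCohort] = {}
    ppvs: dict[str, ValidityEstimate] = {}
    se_inds: dict[str, ValidityEstimate] = {}
    counts: dict[str, dict[int, int]] = {}
    for name, version in ruleset.algorithms.items():
        cohort = build_cohort(records, version, window, residency)
        cohorts[name] = cohort
        counts[name] = annual_case_counts(cohort)
        ppvs[name] = review_ppv(cohort, adjudicated)
        se_inds[name] = treatment_se_indicator(cohort, treatments, residency)
    return StudyResult(
        cohorts=cohorts,
        annual_counts=counts,
        ppv=ppvs,
        se_indicator=se_inds,
        kappa=interrater_kappa(reviews),
    )
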