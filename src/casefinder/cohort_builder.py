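"""Patient-level case cohorts from record-level algorithm flags.

A patient becomes a case if at least one of their registry records inside
the study window satisfies the algorithm; the earliest such record is the
patient's *index record* and fixes the incidence year.  The residency
restriction is applied before evaluation, mirroring the linkage of registry
extracts to the regional inhabitant registry.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Mapping

from .phenotype_engine import AlgorithmVersion, evaluate_algorithm
from .registry_model import PathologyRecord, ResidencyIndex, filter_residents

__all__ = ["CaseCohort", "build_cohort", "annual_case_counts"]


@dataclass(frozen=True)
class CaseCohort:
    """Map patient -> index record for one algorithm version and study window."""

    cases: Mapping[str, PathologyRecord]
    algorithm_name: str
    window: tuple[_dt.date, _dt.date]

    def __len__(self) -> int:
        return len(self.cases)

    def patient_ids(self) -> set[str]:
        return set(self.cases)


def build_cohort(
    records: Iterable[PathologyRecord],
    version: AlgorithmVersion,
    window: tuple[_dt.date, _dt.date],
    index: ResidencyIndex | None = None,
) -> CaseCohort:
    """Build the case cohort: residency filter, record flags, first-record rule.

    The window is closed on both ends.  Ties between same-day records of one
    patient break on lexicographically smallest record_id, so the result is
    invariant to input order.
    """
    start, end = window
    if start > end:
        raise ValueError(f"study window start {start} is after end {end}")
    pool = list(records)
    if index is not None:
        pool = filter_residents(pool, index)
    best: dict[str, PathologyRecord] = {}
    for record in pool:
        if not (start <= record.sample_date <= end):
            continue
        if not evaluate_algorithm(record, version):
            continue
        incumbent = best.get(record.patient_id)
        if incumbent is None or (record.sample_date, record.record_id) < (
            incumbent.sample_date,
            incumbent.record_id,
        ):
            best[record.patient_id] = record
    return CaseCohort(cases=best, algorithm_name=version.name, window=(start, end))


def annual_case_counts(cohort: CaseCohort) -> dict[int, int]:
    """Incident cases per calendar year of the index record, zero-filled."""
    start, end = cohort.window
    counts = {year: 0 for year in range(start.year, end.year + 1)}
    for record in cohort.cases.values():
        counts[record.sample_date.year] += 1
    return counts
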