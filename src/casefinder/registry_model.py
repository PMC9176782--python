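"""Domain types and delimited-text IO for pathology-registry data.

The registry extract is a flat CSV with one row per pathology record.  A
record carries the patient pseudonym, the sample date, SNOMED morphology
(``M-``) and topography (``T-``) codes — several codes per axis are packed
into one cell, semicolon-separated — and five free-text fields (diagnosis,
macroscopy, microscopy, clinical information, sent material).

Companion tables follow the same conventions: a person index with a
residency flag, a mid-year population series, a hospital-pharmacy treatment
table (one row per drug administration, with indication of use), and
manual-review forms (four yes/no/maybe items per record per rater).

All files are UTF-8, dates are ISO-8601, and unknown extra columns are
ignored with a logged warning so that locally enriched extracts still load.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PathologyRecord",
    "ResidencyIndex",
    "TreatmentRecord",
    "ReviewForm",
    "RegistryReadError",
    "REVIEW_LEVELS",
    "REVIEW_ITEMS",
    "DEFAULT_INDICATIONS",
    "read_registry",
    "write_registry",
    "read_treatments",
    "write_treatments",
    "read_persons",
    "write_persons",
    "read_population",
    "write_population",
    "read_reviews",
    "write_reviews",
    "filter_residents",
]


class RegistryReadError(ValueError):
    """A delimited-text extract violates its declared schema."""


REVIEW_LEVELS = ("yes", "no", "maybe")

#: The four manual-review items, in form order.
REVIEW_ITEMS = ("malignancy", "lung_topography", "nsclc_morphology", "primary_origin")

#: Closed vocabulary for the treatment table's indication column.
DEFAULT_INDICATIONS = frozenset({"NSCLC", "OTHER"})


@dataclass
class PathologyRecord:
    """One pathology-registry row: codes plus the five free-text fields."""

    record_id: str
    patient_id: str
    sample_date: _dt.date
    morphology_codes: list[str] = field(default_factory=list)
    topography_codes: list[str] = field(default_factory=list)
    diagnosis_text: str = ""
    macroscopy_text: str = ""
    microscopy_text: str = ""
    clinical_info_text: str = ""
    sent_material_text: str = ""

    def __post_init__(self) -> None:
        if not self.record_id or not self.patient_id:
            raise ValueError("record_id and patient_id are mandatory")
        if not isinstance(self.sample_date, _dt.date):
            raise TypeError("sample_date must be a datetime.date")
        for code in self.morphology_codes:
            if not code.startswith("M-"):
                raise ValueError(f"morphology code {code!r} must start with 'M-'")
        for code in self.topography_codes:
            if not code.startswith("T-"):
                raise ValueError(f"topography code {code!r} must start with 'T-'")


@dataclass(frozen=True)
class ResidencyIndex:
    """Resident patient set plus mid-year population denominators."""

    resident_ids: frozenset[str]
    population_by_year: Mapping[int, int]

    def __post_init__(self) -> None:
        years = sorted(self.population_by_year)
        if years:
            if any(n <= 0 for n in self.population_by_year.values()):
                raise ValueError("population counts must be positive")
            if years != list(range(years[0], years[-1] + 1)):
                raise ValueError("population years must form a contiguous range")

    def is_resident(self, patient_id: str) -> bool:
        return patient_id in self.resident_ids


@dataclass(frozen=True)
class TreatmentRecord:
    """One hospital-pharmacy drug administration (an event, so duplicates count)."""

    patient_id: str
    administration_date: _dt.date
    drug_name: str
    indication: str


@dataclass(frozen=True)
class ReviewForm:
    """Four-item manual review of one record by one rater (yes/no/maybe each)."""

    record_id: str
    rater_id: str
    malignancy: str
    lung_topography: str
    nsclc_morphology: str
    primary_origin: str

    def __post_init__(self) -> None:
        for item in REVIEW_ITEMS:
            level = getattr(self, item)
            if level not in REVIEW_LEVELS:
                raise ValueError(
                    f"review item {item!r} must be one of {REVIEW_LEVELS}, got {level!r}"
                )

    def items(self) -> tuple[str, str, str, str]:
        return tuple(getattr(self, item) for item in REVIEW_ITEMS)


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "record_id",
    "patient_id",
    "sample_date",
    "morphology_codes",
    "topography_codes",
    "diagnosis_text",
    "macroscopy_text",
    "microscopy_text",
    "clinical_info_text",
    "sent_material_text",
]
TREATMENT_COLUMNS = ["patient_id", "administration_date", "drug_name", "indication"]
PERSON_COLUMNS = ["patient_id", "resident_flag"]
POPULATION_COLUMNS = ["year", "population"]
REVIEW_COLUMNS = ["record_id", "rater_id", *REVIEW_ITEMS]


def _read_table(path: str | Path, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise RegistryReadError(f"{what} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RegistryReadError(f"{what} file {path} is missing column(s): {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s file %s: ignoring unknown column(s) %s", what, path, extra)
    return df


def _parse_date(value: str, row: int, column: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value.strip())
    except ValueError as exc:
        raise RegistryReadError(
            f"row {row}: malformed {column} {value!r} (expected YYYY-MM-DD)"
        ) from exc


def _split_codes(cell: str, prefix: str, row: int) -> list[str]:
    codes = []
    for raw in cell.split(";"):
        code = raw.strip().upper()
        if not code:
            continue
        if not code.startswith(prefix):
            raise RegistryReadError(
                f"row {row}: code {raw!r} does not carry the {prefix!r} axis prefix"
            )
        codes.append(code)
    return codes


def read_registry(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[PathologyRecord]:
    """Read a pathology-registry extract.

    ``columns`` optionally maps canonical column names to the names used in
    the file, for extracts whose headers differ from the documented schema.
    Codes are normalized (uppercased, whitespace-stripped, split on ``;``)
    and missing text cells become empty strings.  Row numbers in error
    messages count data rows from 1.
    """
    rename = dict(columns or {})
    df = _read_table(path, [rename.get(c, c) for c in RECORD_COLUMNS], "registry")
    if rename:
        df = df.rename(columns={v: k for k, v in rename.items()})
    records: list[PathologyRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if not row.record_id.strip():
            raise RegistryReadError(f"row {i}: missing record_id")
        if not row.patient_id.strip():
            raise RegistryReadError(f"row {i}: missing patient_id")
        records.append(
            PathologyRecord(
                record_id=row.record_id.strip(),
                patient_id=row.patient_id.strip(),
                sample_date=_parse_date(row.sample_date, i, "sample_date"),
                morphology_codes=_split_codes(row.morphology_codes, "M-", i),
                topography_codes=_split_codes(row.topography_codes, "T-", i),
                diagnosis_text=row.diagnosis_text,
                macroscopy_text=row.macroscopy_text,
                microscopy_text=row.microscopy_text,
                clinical_info_text=row.clinical_info_text,
                sent_material_text=row.sent_material_text,
            )
        )
    return records


def write_registry(records: Iterable[PathologyRecord], path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "patient_id": r.patient_id,
            "sample_date": r.sample_date.isoformat(),
            "morphology_codes": ";".join(r.morphology_codes),
            "topography_codes": ";".join(r.topography_codes),
            "diagnosis_text": r.diagnosis_text,
            "macroscopy_text": r.macroscopy_text,
            "microscopy_text": r.microscopy_text,
            "clinical_info_text": r.clinical_info_text,
            "sent_material_text": r.sent_material_text,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_treatments(
    path: str | Path, valid_indications: frozenset[str] | set[str] = DEFAULT_INDICATIONS
) -> list[TreatmentRecord]:
    """Read the hospital-pharmacy table; duplicate rows are distinct events."""
    df = _read_table(path, TREATMENT_COLUMNS, "treatments")
    out: list[TreatmentRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if not row.patient_id.strip():
            raise RegistryReadError(f"row {i}: missing patient_id")
        indication = row.indication.strip()
        if indication not in valid_indications:
            raise RegistryReadError(
                f"row {i}: indication {indication!r} not in {sorted(valid_indications)}"
            )
        out.append(
            TreatmentRecord(
                patient_id=row.patient_id.strip(),
                administration_date=_parse_date(row.administration_date, i, "administration_date"),
                drug_name=row.drug_name.strip(),
                indication=indication,
            )
        )
    return out


def write_treatments(treatments: Iterable[TreatmentRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": t.patient_id,
            "administration_date": t.administration_date.isoformat(),
            "drug_name": t.drug_name,
            "indication": t.indication,
        }
        for t in treatments
    ]
    pd.DataFrame(rows, columns=TREATMENT_COLUMNS).to_csv(path, index=False)


def read_persons(path: str | Path) -> dict[str, bool]:
    """Read the person index as ``patient_id -> resident flag``."""
    df = _read_table(path, PERSON_COLUMNS, "persons")
    persons: dict[str, bool] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        flag = row.resident_flag.strip().lower()
        if flag not in {"0", "1", "true", "false"}:
            raise RegistryReadError(f"row {i}: resident_flag must be 0/1/true/false")
        persons[row.patient_id.strip()] = flag in {"1", "true"}
    return persons


def write_persons(persons: Mapping[str, bool], path: str | Path) -> None:
    rows = [{"patient_id": pid, "resident_flag": int(flag)} for pid, flag in persons.items()]
    pd.DataFrame(rows, columns=PERSON_COLUMNS).to_csv(path, index=False)


def read_population(path: str | Path) -> dict[int, int]:
    df = _read_table(path, POPULATION_COLUMNS, "population")
    out: dict[int, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out[int(row.year)] = int(row.population)
        except ValueError as exc:
            raise RegistryReadError(f"row {i}: year and population must be integers") from exc
    return out


def write_population(population_by_year: Mapping[int, int], path: str | Path) -> None:
    rows = [{"year": y, "population": n} for y, n in sorted(population_by_year.items())]
    pd.DataFrame(rows, columns=POPULATION_COLUMNS).to_csv(path, index=False)


def read_reviews(path: str | Path) -> list[ReviewForm]:
    df = _read_table(path, REVIEW_COLUMNS, "reviews")
    forms: list[ReviewForm] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            forms.append(
                ReviewForm(
                    record_id=row.record_id.strip(),
                    rater_id=row.rater_id.strip(),
                    malignancy=row.malignancy.strip().lower(),
                    lung_topography=row.lung_topography.strip().lower(),
                    nsclc_morphology=row.nsclc_morphology.strip().lower(),
                    primary_origin=row.primary_origin.strip().lower(),
                )
            )
        except ValueError as exc:
            raise RegistryReadError(f"row {i}: {exc}") from exc
    return forms


def write_reviews(forms: Iterable[ReviewForm], path: str | Path) -> None:
    rows = [
        {
            "record_id": f.record_id,
            "rater_id": f.rater_id,
            **{item: getattr(f, item) for item in REVIEW_ITEMS},
        }
        for f in forms
    ]
    pd.DataFrame(rows, columns=REVIEW_COLUMNS).to_csv(path, index=False)


def filter_residents(
    records: Iterable[PathologyRecord], index: ResidencyIndex
) -> list[PathologyRecord]:
    """Keep only records of resident patients, preserving input order.

    Mirrors the linkage step in which registry records are joined to the
    regional inhabitant registry and non-residents drop out.
    """
    return [r for r in records if index.is_resident(r.patient_id)]
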