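"""Patient-level cohort schema and CSV input/output.

A cohort is one row per thrombolysed patient with the pre-treatment
clinical variables needed by the four stroke-mimic prediction scales,
plus the adjudicated final diagnosis (ischemic stroke, TIA, or mimic).
This schema is the contract for every downstream analysis module.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
LABELS = ("stroke", "tia", "mimic")

#: Boolean clinical-history flags, in schema order.
BOOL_FIELDS = (
    "facial_droop",
    "isolated_sensory_deficit",
    "atrial_fibrillation",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "migraine",
    "seizure_history",
    "psychiatric_history",
)

#: Full CSV column order. The header of every cohort file must match exactly.
FIELD_NAMES = (
    "patient_id",
    "age",
    "sex",
    "sbp",
    "dbp",
    "nihss",
    *BOOL_FIELDS,
    "label",
)

#: Adult inclusion threshold (years).
MIN_AGE = 21

_TRUE_TOKENS = {"1", "true"}
_FALSE_TOKENS = {"0", "false"}


class SchemaError(ValueError):
    """Header or column set does not match the cohort schema."""


class RowError(ValueError):
    """A data row holds an unparseable value (row number and field named)."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's pre-thrombolysis clinical variables and final diagnosis.

    ``facial_droop`` covers both "facial droop" (FABS) and "facial
    weakness" (TeleStroke Mimic); ``seizure_history`` covers "seizure
    disorder", "seizures" and "epilepsy" — the scales were all rated from
    one chart review, so a single flag backs each concept.
    """

    patient_id: str
    age: int
    sex: str
    sbp: int
    dbp: int
    nihss: int
    facial_droop: bool
    isolated_sensory_deficit: bool
    atrial_fibrillation: bool
    hypertension: bool
    hyperlipidemia: bool
    diabetes: bool
    migraine: bool
    seizure_history: bool
    psychiatric_history: bool
    label: str

    def __post_init__(self) -> None:
        if self.age < MIN_AGE:
            raise ValueError(f"age must be >= {MIN_AGE}, got {self.age}")
        if not 0 <= self.nihss <= 42:
            raise ValueError(f"nihss must be in [0, 42], got {self.nihss}")
        if self.sbp <= 0 or self.dbp <= 0:
            raise ValueError("sbp and dbp must be positive")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def is_mimic(self) -> bool:
        return self.label == "mimic"


@dataclass
class Cohort:
    """Ordered patient records plus the count of rows excluded on read."""

    records: list[PatientRecord]
    excluded_count: int = 0

    def __post_init__(self) -> None:
        if self.excluded_count < 0:
            raise ValueError("excluded_count must be >= 0")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_id values must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)


def _parse_bool(token: str, row_num: int, field: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise RowError(f"row {row_num}: field {field!r}: unrecognized boolean {token!r}")


def _parse_int(token: str, row_num: int, field: str) -> int:
    try:
        return int(token.strip())
    except ValueError:
        raise RowError(f"row {row_num}: field {field!r}: not an integer: {token!r}") from None


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV, excluding (and counting) rows with missing fields.

    Rows with an empty required field are counted in ``excluded_count``
    and logged; rows with unparseable values raise :class:`RowError`
    naming the row and field. A header that does not match the schema
    raises :class:`SchemaError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected header row")
        if tuple(reader.fieldnames) != FIELD_NAMES:
            unknown = set(reader.fieldnames) - set(FIELD_NAMES)
            missing = set(FIELD_NAMES) - set(reader.fieldnames)
            raise SchemaError(
                f"{path}: header mismatch (unknown columns {sorted(unknown)}, "
                f"missing columns {sorted(missing)})"
            )
        records: list[PatientRecord] = []
        excluded = 0
        for row_num, row in enumerate(reader, start=2):  # 1 is the header
            blank = [k for k in FIELD_NAMES if row[k] is None or row[k].strip() == ""]
            if blank:
                excluded += 1
                logger.warning("row %d excluded: missing %s", row_num, ", ".join(blank))
                continue
            records.append(_parse_row(row, row_num))
    return Cohort(records=records, excluded_count=excluded)


def _parse_row(row: dict[str, str], row_num: int) -> PatientRecord:
    kwargs: dict[str, object] = {"patient_id": row["patient_id"].strip()}
    for f in ("age", "sbp", "dbp", "nihss"):
        kwargs[f] = _parse_int(row[f], row_num, f)
    sex = row["sex"].strip().lower()
    if sex not in SEXES:
        raise RowError(f"row {row_num}: field 'sex': unrecognized value {row['sex']!r}")
    kwargs["sex"] = sex
    for f in BOOL_FIELDS:
        kwargs[f] = _parse_bool(row[f], row_num, f)
    label = row["label"].strip().lower()
    if label not in LABELS:
        raise RowError(f"row {row_num}: field 'label': unrecognized value {row['label']!r}")
    kwargs["label"] = label
    try:
        return PatientRecord(**kwargs)  # type: ignore[arg-type]
    except ValueError as exc:
        raise RowError(f"row {row_num}: {exc}") from None


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV (booleans as 0/1) such that a read round-trips."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FIELD_NAMES)
        for r in cohort.records:
            row = []
            for f in FIELD_NAMES:
                v = getattr(r, f)
                row.append(int(v) if isinstance(v, bool) else v)
            writer.writerow(row)


def group_sizes(cohort: Cohort, mimic_vs_rest: bool = True) -> tuple[int, int]:
    """Return (true-stroke count, mimic count).

    With ``mimic_vs_rest`` (the default, and the convention of every
    mimic-vs-stroke analysis here) TIA is pooled with ischemic stroke as
    "true stroke"; otherwise only ``label == "stroke"`` counts in the
    first slot and TIA records are counted with neither group's
    complement — the pair is then (stroke, mimic) and need not sum to
    the cohort size.
    """
    n_mimic = sum(r.is_mimic for r in cohort.records)
    if mimic_vs_rest:
        return len(cohort.records) - n_mimic, n_mimic
    return sum(r.label == "stroke" for r in cohort.records), n_mimic


#: Final diagnoses among the 17 stroke mimics of the reference cohort
#: (frequency summary only; functional disorders dominate at 7/17).
MIMIC_FINAL_DIAGNOSES: dict[str, int] = {
    "functional_disorder": 7,
    "migraine": 3,
    "post_ictal_weakness": 2,
    "hypertensive_encephalopathy": 1,
    "delirium": 1,
    "drug_intoxication": 1,
    "cervical_radiculopathy": 1,
    "epidural_hematoma": 1,
}


def records_from_dicts(rows: Iterable[dict]) -> Cohort:
    """Build a cohort from in-memory dicts (test/fixture convenience)."""
    return Cohort(records=[PatientRecord(**row) for row in rows])
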