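"""Patient-record data model, the 15-type operation taxonomy, and CSV I/O.

A record describes one patient's longitudinal history after the first
manifestation of periprosthetic joint infection (PJI): demographics, the
treatment method applied, the dated and priced sequence of surgical
interventions (at most 10), the PJI status at the last observation, and an
optional death date.  Every surgical intervention belongs to one of 15
canonical operation types, grouped by their relation to PJI: unrelated to
PJI, compatible with a first PJI episode or a relapse, or occurring only at
relapse.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "OperationCategory",
    "OperationType",
    "Cohort",
    "TreatmentMethod",
    "OperationEvent",
    "PatientRecord",
    "ClassificationError",
    "RecordValidationError",
    "classify_operation",
    "validate_record",
    "parse_records",
    "write_records",
    "TAXONOMY",
    "SECOND_STAGE_LABEL",
    "SPACER_INSTALLING_LABELS",
    "STUDY_PROVENANCE",
    "MAX_OPERATIONS",
]

MAX_OPERATIONS = 10


class ClassificationError(ValueError):
    """Raised for an operation label outside the canonical taxonomy."""


class RecordValidationError(ValueError):
    """Raised when a CSV source contains rows violating the record schema."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class OperationCategory(Enum):
    """Relation of an operation type to PJI."""

    NO_PJI = "no_pji"
    PJI_FIRST_OR_RELAPSE = "pji_first_or_relapse"
    PJI_RELAPSE_ONLY = "pji_relapse_only"

    @property
    def is_pji_related(self) -> bool:
        return self is not OperationCategory.NO_PJI


@dataclass(frozen=True)
class OperationType:
    label: str
    category: OperationCategory
    is_second_stage: bool = False


SECOND_STAGE_LABEL = "Endoprosthesis (EP) installation + spacer removal"

#: Operations that leave an antibiotic spacer in place; until the spacer is
#: exchanged for a prosthesis the patient is waiting for the second stage.
SPACER_INSTALLING_LABELS = frozenset(
    {"Debridement + spacer installation", "Debridement + spacer reinstallation"}
)

_C = OperationCategory
_TAXONOMY_ROWS: tuple[tuple[str, OperationCategory, bool], ...] = (
    # operations unrelated to PJI
    (SECOND_STAGE_LABEL, _C.NO_PJI, True),
    ("EP installation (no spacer)", _C.NO_PJI, False),
    ("Non-infectious: spacer dislocation", _C.NO_PJI, False),
    ("Other: (suturing, etc.)", _C.NO_PJI, False),
    ("Non-infectious: periprosthetic fracture case", _C.NO_PJI, False),
    # first case of PJI or PJI relapse
    ("Debridement + spacer installation", _C.PJI_FIRST_OR_RELAPSE, False),
    ("Debridement", _C.PJI_FIRST_OR_RELAPSE, False),
    ("EP components replacement + debridement", _C.PJI_FIRST_OR_RELAPSE, False),
    ("Debridement + full EP replacement", _C.PJI_FIRST_OR_RELAPSE, False),
    (
        "Joint drainage + long-term suppressive antibiotic therapy (ABT)",
        _C.PJI_FIRST_OR_RELAPSE,
        False,
    ),
    # PJI relapse only
    ("Debridement + spacer reinstallation", _C.PJI_RELAPSE_ONLY, False),
    ("Disarticulation", _C.PJI_RELAPSE_ONLY, False),
    ("Spacer removal + support osteotomy", _C.PJI_RELAPSE_ONLY, False),
    ("Debridement + support osteotomy + muscle plastic", _C.PJI_RELAPSE_ONLY, False),
    ("Joint drainage", _C.PJI_RELAPSE_ONLY, False),
)

#: Canonical label -> OperationType, all 15 operation types.
TAXONOMY: dict[str, OperationType] = {
    label: OperationType(label, cat, second) for label, cat, second in _TAXONOMY_ROWS
}


def _normalize_label(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip()).casefold()


_NORMALIZED_TAXONOMY = {_normalize_label(k): v for k, v in TAXONOMY.items()}


def classify_operation(label: str) -> OperationType:
    """Map an operation label to its canonical type.

    Matching is whitespace- and case-insensitive (archival data entry is
    noisy); an unrecognized label raises :class:`ClassificationError`.
    """
    try:
        return _NORMALIZED_TAXONOMY[_normalize_label(label)]
    except KeyError:
        raise ClassificationError(
            f"unknown operation label: {label!r} (not one of the 15 canonical types)"
        ) from None


class Cohort(Enum):
    RETROSPECTIVE = "retrospective"
    PROSPECTIVE = "prospective"


class TreatmentMethod(Enum):
    """The eight PJI treatment strategies compared in the study.

    Each member carries the study cohort in which the method was applied and
    whether it is a two-stage strategy (antibiotic spacer placed first,
    prosthesis installed at a later second-stage intervention).
    """

    RE_THR_PE = ("re-THR-PE", Cohort.RETROSPECTIVE, False)
    TWO_STAGE_GT2M = ("2-stage>2mth", Cohort.RETROSPECTIVE, True)
    TWO_STAGE_2_3WK = ("2-stage-2-3wk", Cohort.PROSPECTIVE, True)
    TWO_STAGE_6_8WK = ("2-stage-6-8wk", Cohort.PROSPECTIVE, True)
    ONE_STAGE = ("1-stage", Cohort.PROSPECTIVE, False)
    RA = ("RA", Cohort.RETROSPECTIVE, False)
    PARTIAL_I = ("Partial-I", Cohort.PROSPECTIVE, False)
    PARTIAL_II = ("Partial-II", Cohort.PROSPECTIVE, True)

    def __init__(self, label: str, cohort: Cohort, is_two_stage: bool):
        self.label = label
        self.cohort = cohort
        self.is_two_stage = is_two_stage

    @classmethod
    def from_label(cls, label: str) -> "TreatmentMethod":
        norm = _normalize_label(label)
        for m in cls:
            if _normalize_label(m.label) == norm:
                return m
        raise ValueError(f"unknown treatment method: {label!r}")


@dataclass(frozen=True)
class OperationEvent:
    date: date
    op_type: OperationType
    cost: float  # rubles

    def __post_init__(self):
        if self.cost < 0:
            raise ValueError(f"operation cost must be non-negative, got {self.cost}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's validated longitudinal history.

    ``utility_increments`` (optional) holds EQ-5D-derived QALY increments, one
    per inter-event interval ending at each operation (so its length equals
    the number of operations).  ``cohort`` defaults to the study cohort of
    the treatment method; it differs only for the historical one-stage
    retrospective group, which is represented in data but excluded from
    analysis.
    """

    id: str
    birthdate: date
    sex: str  # "M" or "F"
    method: TreatmentMethod
    manifestation_date: date
    operations: tuple[OperationEvent, ...] = ()
    last_status: str = "NO_PJI"  # "PJI_PRESENT" or "NO_PJI"
    death_date: date | None = None
    censor_date: date | None = None
    utility_increments: tuple[float, ...] | None = None
    cohort: Cohort | None = None

    def __post_init__(self):
        object.__setattr__(self, "operations", tuple(self.operations))
        if self.utility_increments is not None:
            object.__setattr__(
                self, "utility_increments", tuple(self.utility_increments)
            )
        if self.cohort is None:
            object.__setattr__(self, "cohort", self.method.cohort)
        if self.censor_date is None:
            object.__setattr__(
                self, "censor_date", self.death_date or self.manifestation_date
            )

    @property
    def age_at_manifestation(self) -> float:
        return (self.manifestation_date - self.birthdate).days / 365.25


def validate_record(record: PatientRecord) -> list[str]:
    """Return descriptions of every invariant the record violates (empty if valid)."""
    v: list[str] = []
    if record.sex not in ("M", "F"):
        v.append(f"sex must be 'M' or 'F', got {record.sex!r}")
    if record.last_status not in ("PJI_PRESENT", "NO_PJI"):
        v.append(f"last_status must be 'PJI_PRESENT' or 'NO_PJI', got {record.last_status!r}")
    ops = record.operations
    if len(ops) > MAX_OPERATIONS:
        v.append(
            f"{len(ops)} operations exceed the cap of {MAX_OPERATIONS} per record"
        )
    dates = [op.date for op in ops]
    if any(b < a for a, b in zip(dates, dates[1:])):
        v.append("operations are not sorted by non-decreasing date")
    if any(d < record.manifestation_date for d in dates):
        v.append("an operation predates the manifestation date")
    if any(op.cost < 0 for op in ops):
        v.append("an operation has negative cost")
    if record.birthdate > record.manifestation_date:
        v.append("birthdate is after the manifestation date")
    if record.death_date is not None:
        if dates and record.death_date < max(dates):
            v.append("death_date is earlier than the last operation date")
        if record.death_date < record.manifestation_date:
            v.append("death_date is earlier than the manifestation date")
    if record.censor_date is not None and record.censor_date < record.manifestation_date:
        v.append("censor_date is earlier than the manifestation date")
    if record.utility_increments is not None:
        if len(record.utility_increments) != len(ops):
            v.append(
                "utility_increments length does not match the number of operations"
            )
        if any(u < 0 for u in record.utility_increments):
            v.append("a utility increment is negative")
    return v


#: Record-collection arithmetic of the source study: 603 retrospective
#: histories pulled from the archive, of which 25 were verified in person,
#: 356 by phone and 53 by mail; 169 had unknown outcomes and were dropped,
#: leaving 434 retained retrospective records.  166 prospective records were
#: followed in real time.
STUDY_PROVENANCE = {
    "retrospective_initial": 603,
    "retrospective_excluded": 169,
    "retrospective_retained": 434,
    "in_person": 25,
    "by_phone": 356,
    "by_mail": 53,
    "prospective": 166,
}

_CSV_COLUMNS = [
    "patient_id",
    "birthdate",
    "sex",
    "treatment_method",
    "cohort",
    "manifestation_date",
    "op_date",
    "op_label",
    "op_cost_rub",
    "last_status",
    "death_date",
    "censor_date",
    "utility_increment",
]


def _parse_date(value: str, what: str, row: int, errors: list[str]) -> date | None:
    try:
        return date.fromisoformat(value)
    except ValueError:
        errors.append(f"row {row}: malformed {what} {value!r} (expected YYYY-MM-DD)")
        return None


def parse_records(source) -> list[PatientRecord]:
    """Parse a CSV stream/path (one row per operation) into validated records.

    Rows sharing ``patient_id`` form one record; rows with empty operation
    fields describe surgery-free patients.  All per-row problems are
    collected and raised together as :class:`RecordValidationError`.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns and c not in ("cohort", "utility_increment")]
    if missing:
        raise RecordValidationError([f"missing required columns: {missing}"])

    errors: list[str] = []
    records: list[PatientRecord] = []
    for pid, group in df.groupby("patient_id", sort=False):
        first = group.iloc[0]
        row0 = int(group.index[0])
        birth = _parse_date(first["birthdate"], "birthdate", row0, errors)
        manifest = _parse_date(first["manifestation_date"], "manifestation_date", row0, errors)
        censor = _parse_date(first["censor_date"], "censor_date", row0, errors)
        death = None
        if first["death_date"]:
            death = _parse_date(first["death_date"], "death_date", row0, errors)
        try:
            method = TreatmentMethod.from_label(first["treatment_method"])
        except ValueError as exc:
            errors.append(f"row {row0}: {exc}")
            continue
        cohort = method.cohort
        if "cohort" in group.columns and first["cohort"]:
            try:
                cohort = Cohort(first["cohort"])
            except ValueError:
                errors.append(f"row {row0}: unknown cohort {first['cohort']!r}")

        ops: list[OperationEvent] = []
        utils: list[float] = []
        any_utils = False
        for idx, row in group.iterrows():
            if not row["op_date"] and not row["op_label"]:
                continue  # surgery-free placeholder row
            d = _parse_date(row["op_date"], "op_date", int(idx), errors)
            try:
                op_type = classify_operation(row["op_label"])
            except ClassificationError as exc:
                errors.append(f"row {int(idx)}: {exc}")
                continue
            try:
                cost = float(row["op_cost_rub"]) if row["op_cost_rub"] else 0.0
            except ValueError:
                errors.append(f"row {int(idx)}: malformed op_cost_rub {row['op_cost_rub']!r}")
                continue
            if d is None:
                continue
            try:
                ops.append(OperationEvent(d, op_type, cost))
            except ValueError as exc:
                errors.append(f"row {int(idx)}: {exc}")
                continue
            u = row.get("utility_increment", "")
            if u:
                any_utils = True
                try:
                    utils.append(float(u))
                except ValueError:
                    errors.append(f"row {int(idx)}: malformed utility_increment {u!r}")
                    utils.append(0.0)
            else:
                utils.append(0.0)

        if birth is None or manifest is None or censor is None:
            continue
        record = PatientRecord(
            id=str(pid),
            birthdate=birth,
            sex=first["sex"],
            method=method,
            manifestation_date=manifest,
            operations=tuple(ops),
            last_status=first["last_status"],
            death_date=death,
            censor_date=censor,
            utility_increments=tuple(utils) if any_utils else None,
            cohort=cohort,
        )
        violations = validate_record(record)
        if violations:
            errors.extend(f"row {row0} (patient {pid}): {m}" for m in violations)
        else:
            records.append(record)
    if errors:
        raise RecordValidationError(errors)
    return records


def write_records(records: Iterable[PatientRecord], dest=None) -> str | None:
    """Write records as CSV (one row per operation). Returns CSV text if dest is None."""
    rows = []
    for r in records:
        base = {
            "patient_id": r.id,
            "birthdate": r.birthdate.isoformat(),
            "sex": r.sex,
            "treatment_method": r.method.label,
            "cohort": r.cohort.value,
            "manifestation_date": r.manifestation_date.isoformat(),
            "last_status": r.last_status,
            "death_date": r.death_date.isoformat() if r.death_date else "",
            "censor_date": r.censor_date.isoformat(),
        }
        if not r.operations:
            rows.append({**base, "op_date": "", "op_label": "", "op_cost_rub": "", "utility_increment": ""})
            continue
        for i, op in enumerate(r.operations):
            u = ""
            if r.utility_increments is not None:
                u = repr(r.utility_increments[i])
            rows.append(
                {
                    **base,
                    "op_date": op.date.isoformat(),
                    "op_label": op.op_type.label,
                    "op_cost_rub": repr(op.cost),
                    "utility_increment": u,
                }
            )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    if dest is None:
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    df.to_csv(dest, index=False)
    return None
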