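"""Domain types, table schemas and delimited-text I/O for registry extracts.

The pipeline works on five tables that mirror the structure of a national
arthroplasty register linked to a national hospital-contact register:

* ``tha`` — one row per primary total hip arthroplasty (THA),
* ``contacts`` — post-operative hospital contacts carrying coded diagnoses
  and procedures with per-code laterality,
* ``revisions`` — revision procedures,
* ``vitals`` — death / emigration dates,
* ``gold_events`` — the reference standard of verified dislocation events.

All tables are exchanged as delimited text (comma by default) with ISO-8601
dates and an explicit ``unknown`` laterality token.  Diagnosis and procedure
codes on a contact are serialised as ``CODE:laterality`` pairs joined by
``;`` (codes never contain either character).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "Side",
    "Laterality",
    "DiagnosisGroup",
    "Source",
    "RevisionCause",
    "EndReason",
    "Reduction",
    "CodedEntry",
    "ThaRecord",
    "HospitalContact",
    "RevisionRecord",
    "VitalRecord",
    "GoldEvent",
    "FollowUpWindow",
    "TwoByTwo",
    "ProportionEstimate",
    "RegistryBundle",
    "Violation",
    "SchemaError",
    "RowParseError",
    "RecordValidationError",
    "DataError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "validate_bundle",
]


class SchemaError(ValueError):
    """Header of a delimited file does not match the declared schema."""


class RowParseError(ValueError):
    """A row could not be parsed; carries the 1-based data row number."""

    def __init__(self, row_number: int, message: str):
        self.row_number = row_number
        super().__init__(f"row {row_number}: {message}")


class RecordValidationError(ValueError):
    """Records violate schema invariants; lists the offending record ids."""

    def __init__(self, record_ids: Sequence[str], message: str):
        self.record_ids = list(record_ids)
        super().__init__(f"{message}: {', '.join(self.record_ids)}")


class DataError(ValueError):
    """Cross-record inconsistency that prevents computation."""


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Laterality(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


class DiagnosisGroup(str, Enum):
    PRIMARY_OA = "primary_oa"
    ACUTE_FNF = "acute_fnf"
    FRACTURE_SEQUELAE = "fracture_sequelae"
    DYSPLASIA = "dysplasia"
    FEMORAL_HEAD_NECROSIS = "femoral_head_necrosis"
    OTHER = "other"


class Source(str, Enum):
    ARTHROPLASTY_REGISTER = "arthroplasty_register"
    FRACTURE_REGISTER = "fracture_register"


class RevisionCause(str, Enum):
    DISLOCATION = "dislocation"
    OTHER = "other"


class EndReason(str, Enum):
    HORIZON = "horizon"
    REVISION = "revision"
    DEATH = "death"
    MIGRATION = "migration"


class Reduction(str, Enum):
    CLOSED = "closed"
    OPEN = "open"


@dataclass(frozen=True, slots=True)
class CodedEntry:
    """A single coded diagnosis or procedure with its laterality marker."""

    code: str
    laterality: Laterality = Laterality.UNKNOWN


@dataclass(slots=True)
class ThaRecord:
    """One primary THA: the unit of analysis."""

    patient_id: str
    side: Side
    surgery_date: date
    diagnosis_group: DiagnosisGroup
    hospital_id: str
    source: Source = Source.ARTHROPLASTY_REGISTER

    def problems(self) -> list[str]:
        out = []
        if not self.patient_id:
            out.append("empty patient_id")
        return out


@dataclass(slots=True)
class HospitalContact:
    """One post-operative hospital contact.

    ``admission_link_id`` groups the contacts of one clinical course, so a
    department/hospital transfer produces a second contact with the same
    link id.  ``n_dislocations_in_admission`` is a gold annotation available
    only for synthetic data (0 for noise contacts); real extracts leave it 0.
    """

    contact_id: str
    patient_id: str
    start_date: date
    hospital_id: str
    admission_link_id: str
    diagnosis_codes: list[CodedEntry] = field(default_factory=list)
    procedure_codes: list[CodedEntry] = field(default_factory=list)
    n_dislocations_in_admission: int = 0

    def problems(self) -> list[str]:
        out = []
        if self.n_dislocations_in_admission < 0:
            out.append("negative n_dislocations_in_admission")
        for entry in list(self.diagnosis_codes) + list(self.procedure_codes):
            if not entry.code:
                out.append("empty code string")
        return out


@dataclass(slots=True)
class RevisionRecord:
    patient_id: str
    side: Side
    date: date
    cause: RevisionCause = RevisionCause.OTHER

    def problems(self) -> list[str]:
        return []


@dataclass(slots=True)
class VitalRecord:
    patient_id: str
    death_date: Optional[date] = None
    migration_date: Optional[date] = None

    def problems(self) -> list[str]:
        return []


@dataclass(slots=True)
class GoldEvent:
    """A verified dislocation event: the reference standard."""

    patient_id: str
    side: Side
    event_date: date
    reduction: Reduction = Reduction.CLOSED
    admission_link_id: str = ""

    def problems(self) -> list[str]:
        return []


@dataclass(frozen=True, slots=True)
class FollowUpWindow:
    """Closed follow-up window [start, end]; an event on ``start`` counts."""

    start: date
    end: date
    end_reason: EndReason = EndReason.HORIZON

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"window start {self.start} after end {self.end}")

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end

    @property
    def days(self) -> int:
        return (self.end - self.start).days


@dataclass(frozen=True, slots=True)
class TwoByTwo:
    """Patient-level confusion counts against the reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True, slots=True)
class ProportionEstimate:
    """A k/n proportion with an exact two-sided confidence interval.

    Percentages are stored rounded half-up to one decimal, which is the
    precision used in all rendered tables.
    """

    k: int
    n: int
    point_pct: float
    ci_low_pct: float
    ci_high_pct: float
    method: str = "clopper-pearson"

    def __post_init__(self):
        if not 0 <= self.k <= self.n:
            raise ValueError(f"require 0 <= k <= n, got k={self.k}, n={self.n}")
        if not (0.0 <= self.ci_low_pct <= self.point_pct + 1e-9
                and self.point_pct - 1e-9 <= self.ci_high_pct <= 100.0):
            raise ValueError("interval must bracket the point estimate in [0, 100]")

    def __str__(self) -> str:
        return f"{self.point_pct:.1f} ({self.ci_low_pct:.1f}-{self.ci_high_pct:.1f})"


@dataclass(slots=True)
class RegistryBundle:
    """All five tables of one registry extract plus generation provenance."""

    thas: list[ThaRecord]
    contacts: list[HospitalContact]
    revisions: list[RevisionRecord]
    vitals: list[VitalRecord]
    gold_events: list[GoldEvent]
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True, slots=True)
class Violation:
    table: str
    record_id: str
    message: str


# ---------------------------------------------------------------------------
# Delimited-text schemas
# ---------------------------------------------------------------------------

_CODELIST_SEP = ";"
_CODE_SIDE_SEP = ":"


def _fmt_date(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def _parse_date(text: str, *, optional: bool = False) -> Optional[date]:
    text = text.strip()
    if not text:
        if optional:
            return None
        raise ValueError("empty date field")
    try:
        return date.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"unparseable date {text!r}") from exc


def _parse_laterality(text: str) -> Laterality:
    text = text.strip().lower()
    try:
        return Laterality(text)
    except ValueError:
        return Laterality.UNKNOWN


def _fmt_codes(entries: Iterable[CodedEntry]) -> str:
    return _CODELIST_SEP.join(
        f"{e.code}{_CODE_SIDE_SEP}{e.laterality.value}" for e in entries
    )


def _parse_codes(text: str) -> list[CodedEntry]:
    text = text.strip()
    if not text:
        return []
    out = []
    for token in text.split(_CODELIST_SEP):
        code, sep, lat = token.partition(_CODE_SIDE_SEP)
        if not code:
            raise ValueError(f"empty code in token {token!r}")
        out.append(CodedEntry(code, _parse_laterality(lat) if sep else Laterality.UNKNOWN))
    return out


def _tha_to_row(r: ThaRecord) -> list[str]:
    return [r.patient_id, r.side.value, r.surgery_date.isoformat(),
            r.diagnosis_group.value, r.hospital_id, r.source.value]


def _tha_from_row(row: dict[str, str]) -> ThaRecord:
    return ThaRecord(
        patient_id=row["patient_id"],
        side=Side(row["side"]),
        surgery_date=_parse_date(row["surgery_date"]),
        diagnosis_group=DiagnosisGroup(row["diagnosis_group"]),
        hospital_id=row["hospital_id"],
        source=Source(row["source"]),
    )


def _contact_to_row(c: HospitalContact) -> list[str]:
    return [c.contact_id, c.patient_id, c.start_date.isoformat(), c.hospital_id,
            c.admission_link_id, _fmt_codes(c.diagnosis_codes),
            _fmt_codes(c.procedure_codes), str(c.n_dislocations_in_admission)]


def _contact_from_row(row: dict[str, str]) -> HospitalContact:
    return HospitalContact(
        contact_id=row["contact_id"],
        patient_id=row["patient_id"],
        start_date=_parse_date(row["start_date"]),
        hospital_id=row["hospital_id"],
        admission_link_id=row["admission_link_id"],
        diagnosis_codes=_parse_codes(row["diagnosis_codes"]),
        procedure_codes=_parse_codes(row["procedure_codes"]),
        n_dislocations_in_admission=int(row["n_dislocations_in_admission"] or 0),
    )


def _revision_to_row(r: RevisionRecord) -> list[str]:
    return [r.patient_id, r.side.value, r.date.isoformat(), r.cause.value]


def _revision_from_row(row: dict[str, str]) -> RevisionRecord:
    return RevisionRecord(
        patient_id=row["patient_id"],
        side=Side(row["side"]),
        date=_parse_date(row["date"]),
        cause=RevisionCause(row["cause"]),
    )


def _vital_to_row(r: VitalRecord) -> list[str]:
    return [r.patient_id, _fmt_date(r.death_date), _fmt_date(r.migration_date)]


def _vital_from_row(row: dict[str, str]) -> VitalRecord:
    return VitalRecord(
        patient_id=row["patient_id"],
        death_date=_parse_date(row["death_date"], optional=True),
        migration_date=_parse_date(row["migration_date"], optional=True),
    )


def _gold_to_row(e: GoldEvent) -> list[str]:
    return [e.patient_id, e.side.value, e.event_date.isoformat(),
            e.reduction.value, e.admission_link_id]


def _gold_from_row(row: dict[str, str]) -> GoldEvent:
    return GoldEvent(
        patient_id=row["patient_id"],
        side=Side(row["side"]),
        event_date=_parse_date(row["event_date"]),
        reduction=Reduction(row["reduction"]),
        admission_link_id=row["admission_link_id"],
    )


@dataclass(frozen=True)
class _Schema:
    name: str
    columns: tuple[str, ...]
    record_type: type
    to_row: callable
    from_row: callable
    id_field: str


SCHEMAS: dict[str, _Schema] = {
    s.name: s
    for s in [
        _Schema("tha",
                ("patient_id", "side", "surgery_date", "diagnosis_group",
                 "hospital_id", "source"),
                ThaRecord, _tha_to_row, _tha_from_row, "patient_id"),
        _Schema("contacts",
                ("contact_id", "patient_id", "start_date", "hospital_id",
                 "admission_link_id", "diagnosis_codes", "procedure_codes",
                 "n_dislocations_in_admission"),
                HospitalContact, _contact_to_row, _contact_from_row, "contact_id"),
        _Schema("revisions",
                ("patient_id", "side", "date", "cause"),
                RevisionRecord, _revision_to_row, _revision_from_row, "patient_id"),
        _Schema("vitals",
                ("patient_id", "death_date", "migration_date"),
                VitalRecord, _vital_to_row, _vital_from_row, "patient_id"),
        _Schema("gold_events",
                ("patient_id", "side", "event_date", "reduction",
                 "admission_link_id"),
                GoldEvent, _gold_to_row, _gold_from_row, "patient_id"),
    ]
}


def read_table(path: str | Path, schema: str, delimiter: str = ",") -> list:
    """Read one registry table, returning typed records.

    Raises :class:`SchemaError` if the header is missing a required column or
    carries an undeclared one, and :class:`RowParseError` (with the 1-based
    data row number) for unparseable cells.
    """
    sch = SCHEMAS[schema]
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header {sch.columns}")
        missing = [c for c in sch.columns if c not in header]
        extra = [c for c in header if c not in sch.columns]
        if missing or extra:
            parts = []
            if missing:
                parts.append("missing column(s): " + ", ".join(missing))
            if extra:
                parts.append("unexpected column(s): " + ", ".join(extra))
            raise SchemaError(f"{path} does not match schema {schema!r}: "
                              + "; ".join(parts))
        index = {c: header.index(c) for c in sch.columns}
        records = []
        for i, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                record = sch.from_row({c: row[j] for c, j in index.items()})
            except (ValueError, IndexError, KeyError) as exc:
                raise RowParseError(i, str(exc)) from exc
            records.append(record)
    return records


def write_table(records: Sequence, path: str | Path, schema: str,
                delimiter: str = ",") -> None:
    """Write records in deterministic column order, validating invariants.

    Raises :class:`RecordValidationError` naming every offending record if
    any record violates its own invariants.
    """
    sch = SCHEMAS[schema]
    bad = []
    for r in records:
        if not isinstance(r, sch.record_type):
            raise TypeError(
                f"schema {schema!r} expects {sch.record_type.__name__}, "
                f"got {type(r).__name__}")
        if r.problems():
            bad.append(str(getattr(r, sch.id_field)))
    if bad:
        raise RecordValidationError(bad, f"invalid records for schema {schema!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(sch.columns)
        for r in records:
            writer.writerow(sch.to_row(r))


# ---------------------------------------------------------------------------
# Cross-table validation
# ---------------------------------------------------------------------------


def validate_bundle(bundle: RegistryBundle) -> list[Violation]:
    """Check cross-table invariants; returns one violation per defect.

    Checks: duplicate (patient, side) THAs, orphan contacts / gold events,
    revisions dated before the matching surgery, gold events before surgery,
    duplicate vital rows, negative admission dislocation counts, and
    dislocation-annotated contacts with no matching gold event.
    """
    violations: list[Violation] = []
    tha_by_key: dict[tuple[str, Side], ThaRecord] = {}
    patients = set()
    for t in bundle.thas:
        key = (t.patient_id, t.side)
        if key in tha_by_key:
            violations.append(Violation(
                "tha", t.patient_id,
                f"duplicate THA for patient {t.patient_id} side {t.side.value}"))
        else:
            tha_by_key[key] = t
        patients.add(t.patient_id)

    for c in bundle.contacts:
        if c.patient_id not in patients:
            violations.append(Violation(
                "contacts", c.contact_id,
                f"contact for unknown patient {c.patient_id}"))
        if c.n_dislocations_in_admission < 0:
            violations.append(Violation(
                "contacts", c.contact_id, "negative n_dislocations_in_admission"))

    for r in bundle.revisions:
        tha = tha_by_key.get((r.patient_id, r.side))
        if tha is None:
            violations.append(Violation(
                "revisions", r.patient_id,
                f"revision for unknown THA {r.patient_id}/{r.side.value}"))
        elif r.date < tha.surgery_date:
            violations.append(Violation(
                "revisions", r.patient_id,
                f"revision on {r.date} precedes surgery {tha.surgery_date}"))

    seen_vitals = set()
    for v in bundle.vitals:
        if v.patient_id in seen_vitals:
            violations.append(Violation(
                "vitals", v.patient_id, "duplicate vital record"))
        seen_vitals.add(v.patient_id)

    gold_admissions: dict[tuple[str, str], int] = {}
    for e in bundle.gold_events:
        tha = tha_by_key.get((e.patient_id, e.side))
        if tha is None:
            violations.append(Violation(
                "gold_events", e.patient_id,
                f"gold event for unknown THA {e.patient_id}/{e.side.value}"))
        elif e.event_date < tha.surgery_date:
            violations.append(Violation(
                "gold_events", e.patient_id,
                f"event on {e.event_date} precedes surgery {tha.surgery_date}"))
        key = (e.patient_id, e.admission_link_id)
        gold_admissions[key] = gold_admissions.get(key, 0) + 1

    for c in bundle.contacts:
        if c.n_dislocations_in_admission >= 1:
            n_gold = gold_admissions.get((c.patient_id, c.admission_link_id), 0)
            if n_gold < c.n_dislocations_in_admission:
                violations.append(Violation(
                    "contacts", c.contact_id,
                    f"{c.n_dislocations_in_admission} annotated dislocation(s) "
                    f"but {n_gold} gold event(s) in admission "
                    f"{c.admission_link_id}"))
    return violations


def bundle_to_dir(bundle: RegistryBundle, out_dir: str | Path,
                  delimiter: str = ",") -> dict[str, Path]:
    """Write all five tables of a bundle into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "tha": bundle.thas,
        "contacts": bundle.contacts,
        "revisions": bundle.revisions,
        "vitals": bundle.vitals,
        "gold_events": bundle.gold_events,
    }
    paths = {}
    for name, records in tables.items():
        p = out_dir / f"{name}.csv"
        write_table(records, p, name, delimiter=delimiter)
        paths[name] = p
    return paths


def bundle_from_dir(in_dir: str | Path, delimiter: str = ",") -> RegistryBundle:
    """Read the five standard tables from a directory into a bundle."""
    in_dir = Path(in_dir)
    return RegistryBundle(
        thas=read_table(in_dir / "tha.csv", "tha", delimiter),
        contacts=read_table(in_dir / "contacts.csv", "contacts", delimiter),
        revisions=read_table(in_dir / "revisions.csv", "revisions", delimiter),
        vitals=read_table(in_dir / "vitals.csv", "vitals", delimiter),
        gold_events=read_table(in_dir / "gold_events.csv", "gold_events", delimiter),
    )
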