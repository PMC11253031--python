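"""The staged code-matching classifier for THA dislocation.

A hospital contact identifies a dislocation when a qualifying diagnosis
code and a qualifying reduction procedure code occur together on the same
contact.  The classifier is organised in four cumulative stages that trade
positive predictive value for sensitivity:

* stage 1 — the nominally correct pair: DT84.0A (mechanical complication of
  a hip prosthesis) with a KNFH2* reduction of a dislocated hip prosthesis,
  laterality matching the index hip;
* stage 2 — adds the half-correct pairs DT84.0A x KNFH0* and DS73.0 x
  KNFH2* (native-hip codes applied to a prosthetic dislocation), still
  laterality-matched;
* stage 3 — adds the fully native-coded pair DS73.0 x KNFH0*;
* stage 4 — the stage-3 rules with the laterality requirement relaxed, so
  contacts with unknown or ambiguous laterality are admitted.

Codes are matched as prefixes: KNFH2 covers KNFH20 (closed), KNFH21
(arthroscopic) and KNFH22 (open) reductions.  Stage membership is fully
configurable through a declarative stage specification, and custom
specifications are checked for cumulativity.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Mapping, Optional, Sequence

from .cohort_builder import Cohort
from .registry_model import (
    CodedEntry,
    DataError,
    FollowUpWindow,
    HospitalContact,
    Laterality,
    Side,
    ThaRecord,
)

__all__ = [
    "LateralityRequirement",
    "StageRule",
    "StageConfig",
    "StageSpecError",
    "CodeMatch",
    "PatientFlag",
    "DEFAULT_STAGE_SPEC",
    "compile_stages",
    "match_contact",
    "flag_patients",
]


class StageSpecError(ValueError):
    """A stage specification is malformed or not cumulative."""


class LateralityRequirement(str, Enum):
    MUST_MATCH_INDEX_SIDE = "must_match_index_side"
    ANY = "any"


@dataclass(frozen=True, slots=True)
class StageRule:
    """One (diagnosis prefix, procedure prefix) pair with its laterality rule."""

    dx_pattern: str
    proc_pattern: str
    laterality_requirement: LateralityRequirement = (
        LateralityRequirement.MUST_MATCH_INDEX_SIDE)


@dataclass(frozen=True)
class StageConfig:
    """Ordered, cumulative rule sets for stages 1..n."""

    stages: tuple[tuple[StageRule, ...], ...]

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def rules_at(self, stage: int) -> tuple[StageRule, ...]:
        if not 1 <= stage <= self.n_stages:
            raise ValueError(f"stage must be in 1..{self.n_stages}, got {stage}")
        return self.stages[stage - 1]


@dataclass(frozen=True, slots=True)
class CodeMatch:
    """Classifier verdict for one contact: the minimum qualifying stage."""

    contact_id: str
    stage: Optional[int]
    matched_rule: Optional[StageRule]
    match_date: date


@dataclass(frozen=True, slots=True)
class PatientFlag:
    """Patient-level verdict: flagged iff any in-window contact qualifies."""

    patient_id: str
    flagged: bool
    first_flag_date: Optional[date] = None
    flag_stage: Optional[int] = None


#: Default four-stage specification (see module docstring).  Stage 4 repeats
#: the stage-3 pairs with the laterality requirement relaxed to ``any``.
DEFAULT_STAGE_SPEC: dict = {
    "stages": [
        [
            {"dx": "DT84.0A", "proc": "KNFH2",
             "laterality": "must_match_index_side"},
        ],
        [
            {"dx": "DT84.0A", "proc": "KNFH2",
             "laterality": "must_match_index_side"},
            {"dx": "DT84.0A", "proc": "KNFH0",
             "laterality": "must_match_index_side"},
            {"dx": "DS73.0", "proc": "KNFH2",
             "laterality": "must_match_index_side"},
        ],
        [
            {"dx": "DT84.0A", "proc": "KNFH2",
             "laterality": "must_match_index_side"},
            {"dx": "DT84.0A", "proc": "KNFH0",
             "laterality": "must_match_index_side"},
            {"dx": "DS73.0", "proc": "KNFH2",
             "laterality": "must_match_index_side"},
            {"dx": "DS73.0", "proc": "KNFH0",
             "laterality": "must_match_index_side"},
        ],
        [
            {"dx": "DT84.0A", "proc": "KNFH2", "laterality": "any"},
            {"dx": "DT84.0A", "proc": "KNFH0", "laterality": "any"},
            {"dx": "DS73.0", "proc": "KNFH2", "laterality": "any"},
            {"dx": "DS73.0", "proc": "KNFH0", "laterality": "any"},
        ],
    ]
}


def _rule_from_dict(d: Mapping) -> StageRule:
    try:
        return StageRule(
            dx_pattern=str(d["dx"]),
            proc_pattern=str(d["proc"]),
            laterality_requirement=LateralityRequirement(
                d.get("laterality", "must_match_index_side")),
        )
    except (KeyError, ValueError) as exc:
        raise StageSpecError(f"malformed rule {d!r}: {exc}") from exc


def _covers(later: StageRule, earlier: StageRule) -> bool:
    """True if ``later`` matches every contact that ``earlier`` matches."""
    if (later.dx_pattern, later.proc_pattern) != (
            earlier.dx_pattern, earlier.proc_pattern):
        return False
    return (later.laterality_requirement == earlier.laterality_requirement
            or later.laterality_requirement is LateralityRequirement.ANY)


def compile_stages(stage_spec: Optional[Mapping] = None) -> StageConfig:
    """Compile a declarative stage specification into a :class:`StageConfig`.

    ``None`` compiles the default four-stage specification.  Cumulativity is
    enforced: every rule of stage *s* must be covered by some rule of stage
    *s*+1 (same code pair, equal or weaker laterality requirement).
    """
    spec = DEFAULT_STAGE_SPEC if stage_spec is None else stage_spec
    raw_stages = spec.get("stages") if isinstance(spec, Mapping) else None
    if not raw_stages:
        raise StageSpecError("stage specification must list at least one stage")
    stages = tuple(
        tuple(_rule_from_dict(rule) for rule in stage_rules)
        for stage_rules in raw_stages
    )
    for s in range(len(stages) - 1):
        for rule in stages[s]:
            if not any(_covers(later, rule) for later in stages[s + 1]):
                raise StageSpecError(
                    f"stage {s + 2} is not cumulative: it does not cover rule "
                    f"({rule.dx_pattern} x {rule.proc_pattern}, "
                    f"{rule.laterality_requirement.value}) of stage {s + 1}")
    return StageConfig(stages=stages)


def _pair_satisfies(rule: StageRule, dx: CodedEntry, proc: CodedEntry,
                    index_side: Side) -> bool:
    if not dx.code.startswith(rule.dx_pattern):
        return False
    if not proc.code.startswith(rule.proc_pattern):
        return False
    if rule.laterality_requirement is LateralityRequirement.ANY:
        return True
    # must_match_index_side: at least one code carries the index side and
    # neither carries the contralateral side.
    want = Laterality(index_side.value)
    sides = (dx.laterality, proc.laterality)
    if want not in sides:
        return False
    return all(s in (want, Laterality.UNKNOWN) for s in sides)


def match_contact(contact: HospitalContact, tha: ThaRecord, cfg: StageConfig,
                  window: Optional[FollowUpWindow] = None) -> CodeMatch:
    """Classify one contact: the minimum stage at which some rule matches.

    A rule matches when a diagnosis code with the rule's prefix and a
    procedure code with the rule's prefix co-occur on the contact and the
    laterality requirement holds.  With ``must_match_index_side`` a known
    contralateral side on either code blocks the match (the contact then
    qualifies only at a relaxed-laterality stage).  If ``window`` is given,
    contacts outside it are rejected with :class:`DataError`.
    """
    if contact.patient_id != tha.patient_id:
        raise DataError(
            f"contact {contact.contact_id} belongs to {contact.patient_id}, "
            f"not {tha.patient_id}")
    if window is not None and not window.contains(contact.start_date):
        raise DataError(
            f"contact {contact.contact_id} on {contact.start_date} is outside "
            f"the follow-up window [{window.start}, {window.end}]")
    for stage_number, rules in enumerate(cfg.stages, start=1):
        for rule in rules:
            for dx in contact.diagnosis_codes:
                for proc in contact.procedure_codes:
                    if _pair_satisfies(rule, dx, proc, tha.side):
                        return CodeMatch(contact.contact_id, stage_number,
                                         rule, contact.start_date)
    return CodeMatch(contact.contact_id, None, None, contact.start_date)


def flag_patients(cohort: Cohort, contacts: Sequence[HospitalContact],
                  cfg: StageConfig, stage: int) -> list[PatientFlag]:
    """Patient-level classification at a requested stage.

    A patient is flagged iff at least one contact inside their follow-up
    window matches at a stage <= ``stage``; ``first_flag_date`` is the
    earliest such contact date and ``flag_stage`` the minimum matching stage
    over all their in-window contacts (which may be lower than ``stage``).
    """
    if not 1 <= stage <= cfg.n_stages:
        raise ValueError(f"stage must be in 1..{cfg.n_stages}, got {stage}")
    by_patient: dict[str, list[HospitalContact]] = {}
    for c in contacts:
        by_patient.setdefault(c.patient_id, []).append(c)

    flags: list[PatientFlag] = []
    for tha, window in cohort.members:
        best_stage: Optional[int] = None
        first_date: Optional[date] = None
        for c in by_patient.get(tha.patient_id, ()):
            if not window.contains(c.start_date):
                continue
            m = match_contact(c, tha, cfg)
            if m.stage is None or m.stage > stage:
                continue
            if best_stage is None or m.stage < best_stage:
                best_stage = m.stage
            if first_date is None or c.start_date < first_date:
                first_date = c.start_date
        flags.append(PatientFlag(
            patient_id=tha.patient_id,
            flagged=best_stage is not None,
            first_flag_date=first_date,
            flag_stage=best_stage,
        ))
    return flags


_FLAG_COLUMNS = ("patient_id", "flagged", "first_flag_date", "flag_stage")


def write_flags(flags: Sequence[PatientFlag], path) -> None:
    import csv
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_FLAG_COLUMNS)
        for f in flags:
            w.writerow([f.patient_id, str(f.flagged).lower(),
                        f.first_flag_date.isoformat() if f.first_flag_date else "",
                        f.flag_stage if f.flag_stage is not None else ""])


def read_flags(path) -> list[PatientFlag]:
    import csv
    from pathlib import Path

    from .registry_model import SchemaError

    path = Path(path)
    flags = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != _FLAG_COLUMNS:
            raise SchemaError(f"{path}: expected columns {_FLAG_COLUMNS}")
        for row in reader:
            flags.append(PatientFlag(
                patient_id=row["patient_id"],
                flagged=row["flagged"] == "true",
                first_flag_date=(date.fromisoformat(row["first_flag_date"])
                                 if row["first_flag_date"] else None),
                flag_stage=(int(row["flag_stage"])
                            if row["flag_stage"] else None)))
    return flags


def write_matches(matches: Sequence[CodeMatch], path) -> None:
    import csv
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(("contact_id", "stage", "dx_pattern", "proc_pattern",
                    "laterality_requirement", "match_date"))
        for m in matches:
            rule = m.matched_rule
            w.writerow([
                m.contact_id,
                m.stage if m.stage is not None else "",
                rule.dx_pattern if rule else "",
                rule.proc_pattern if rule else "",
                rule.laterality_requirement.value if rule else "",
                m.match_date.isoformat()])
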