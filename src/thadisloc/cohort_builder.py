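"""Cohort assembly: merge the two source registers, apply exclusions,
and compute censored follow-up windows.

The analysis cohort contains one primary THA per patient, performed inside
the inclusion window.  Follow-up runs from the day of surgery (inclusive)
until the earliest of the 1-year horizon, a same-side revision, death, or
emigration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

from .registry_model import (
    DataError,
    EndReason,
    FollowUpWindow,
    RevisionRecord,
    Side,
    Source,
    ThaRecord,
    VitalRecord,
)

logger = logging.getLogger(__name__)

__all__ = ["Cohort", "merge_sources", "apply_exclusions", "compute_followup",
           "build_cohort", "write_cohort", "read_cohort"]

#: Two records in the arthroplasty and fracture registers are considered the
#: same procedure if patient and side agree and the dates differ by at most
#: this many days (registration-date slack between registers).
MERGE_DATE_SLACK_DAYS = 1

# Tie-break order for simultaneous censoring events.
_REASON_PRECEDENCE = {
    EndReason.REVISION: 0,
    EndReason.DEATH: 1,
    EndReason.MIGRATION: 2,
    EndReason.HORIZON: 3,
}


@dataclass
class Cohort:
    """The analysis cohort: (THA, follow-up window) pairs plus the
    per-rule exclusion counts needed for a flowchart report."""

    members: list[tuple[ThaRecord, FollowUpWindow]]
    inclusion_window: tuple[date, date]
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def records(self) -> list[ThaRecord]:
        return [t for t, _ in self.members]

    @property
    def patient_ids(self) -> set[str]:
        return {t.patient_id for t, _ in self.members}

    def window_of(self, patient_id: str) -> FollowUpWindow:
        for t, w in self.members:
            if t.patient_id == patient_id:
                return w
        raise KeyError(patient_id)


def merge_sources(arthro: Sequence[ThaRecord],
                  fracture: Sequence[ThaRecord]) -> list[ThaRecord]:
    """Union of the arthroplasty-register and fracture-register THAs.

    The fracture register serves only to capture acute-fracture THAs missing
    from the arthroplasty register, so on a key collision — same patient and
    side with surgery dates within ``MERGE_DATE_SLACK_DAYS`` — the
    arthroplasty-register record wins; conflicting diagnosis groups are
    logged but do not block the merge.
    """
    merged = list(arthro)
    by_key: dict[tuple[str, Side], list[ThaRecord]] = {}
    for t in arthro:
        by_key.setdefault((t.patient_id, t.side), []).append(t)

    slack = timedelta(days=MERGE_DATE_SLACK_DAYS)
    for f in fracture:
        duplicates = [
            a for a in by_key.get((f.patient_id, f.side), [])
            if abs(a.surgery_date - f.surgery_date) <= slack
        ]
        if duplicates:
            for a in duplicates:
                if a.diagnosis_group != f.diagnosis_group:
                    logger.warning(
                        "merge_conflict patient=%s side=%s arthro_dx=%s "
                        "fracture_dx=%s kept=arthroplasty_register",
                        f.patient_id, f.side.value,
                        a.diagnosis_group.value, f.diagnosis_group.value)
            continue
        entry = ThaRecord(
            patient_id=f.patient_id, side=f.side, surgery_date=f.surgery_date,
            diagnosis_group=f.diagnosis_group, hospital_id=f.hospital_id,
            source=Source.FRACTURE_REGISTER)
        merged.append(entry)
        # accepted fracture records also take part in later deduplication
        by_key.setdefault((f.patient_id, f.side), []).append(entry)
    return merged


def apply_exclusions(thas: Sequence[ThaRecord],
                     inclusion_window: tuple[date, date]) -> Cohort:
    """Drop out-of-window THAs and in-window contralateral second hips.

    When a patient has two in-window primaries, the earlier operation is
    kept (the later contralateral hip would not have independent follow-up);
    a same-day bilateral pair is broken deterministically in favour of the
    left hip.  Counts per exclusion rule are recorded so that
    ``len(input) == len(cohort) + sum(excluded)`` always reconciles.
    """
    start, end = inclusion_window
    counts = {"outside_window": 0, "contralateral_excluded": 0,
              "duplicate_record": 0}
    in_window: list[ThaRecord] = []
    for t in thas:
        if start <= t.surgery_date <= end:
            in_window.append(t)
        else:
            counts["outside_window"] += 1

    by_patient: dict[str, list[ThaRecord]] = {}
    for t in in_window:
        by_patient.setdefault(t.patient_id, []).append(t)

    kept: list[ThaRecord] = []
    for pid, records in by_patient.items():
        sides = {t.side for t in records}
        if len(records) > len(sides):
            # same patient+side twice in-window: keep the first, count the rest
            deduped: dict[Side, ThaRecord] = {}
            for t in sorted(records, key=lambda t: (t.surgery_date, t.side.value)):
                if t.side in deduped:
                    counts["duplicate_record"] += 1
                else:
                    deduped[t.side] = t
            records = list(deduped.values())
        if len(records) == 1:
            kept.append(records[0])
            continue
        # bilateral in-window: earliest wins, same-day tie broken toward left
        records.sort(key=lambda t: (t.surgery_date,
                                    0 if t.side is Side.LEFT else 1))
        kept.append(records[0])
        counts["contralateral_excluded"] += len(records) - 1
        logger.info("contralateral_exclusion patient=%s kept_side=%s",
                    pid, records[0].side.value)

    kept.sort(key=lambda t: (t.patient_id, t.side.value))
    members = [(t, FollowUpWindow(t.surgery_date, t.surgery_date))
               for t in kept]  # placeholder windows; build_cohort replaces them
    return Cohort(members=members, inclusion_window=inclusion_window,
                  exclusion_counts=counts)


def compute_followup(tha: ThaRecord,
                     revisions: Sequence[RevisionRecord],
                     vitals: Sequence[VitalRecord],
                     horizon_days: int = 365) -> FollowUpWindow:
    """Censored follow-up window for one THA.

    End = the earliest of surgery + ``horizon_days``, the first same-side
    revision, death, and emigration; ties resolve by the precedence
    revision > death > migration > horizon.  A censoring event dated before
    surgery raises :class:`DataError`.
    """
    candidates: list[tuple[date, EndReason]] = [
        (tha.surgery_date + timedelta(days=horizon_days), EndReason.HORIZON)
    ]
    for r in revisions:
        if r.patient_id == tha.patient_id and r.side == tha.side:
            if r.date < tha.surgery_date:
                raise DataError(
                    f"revision for {tha.patient_id} on {r.date} precedes "
                    f"surgery {tha.surgery_date}")
            candidates.append((r.date, EndReason.REVISION))
    for v in vitals:
        if v.patient_id != tha.patient_id:
            continue
        for d, reason in ((v.death_date, EndReason.DEATH),
                          (v.migration_date, EndReason.MIGRATION)):
            if d is None:
                continue
            if d < tha.surgery_date:
                raise DataError(
                    f"{reason.value} for {tha.patient_id} on {d} precedes "
                    f"surgery {tha.surgery_date}")
            candidates.append((d, reason))
    end, reason = min(candidates, key=lambda c: (c[0], _REASON_PRECEDENCE[c[1]]))
    return FollowUpWindow(start=tha.surgery_date, end=end, end_reason=reason)


def build_cohort(arthro: Sequence[ThaRecord],
                 fracture: Sequence[ThaRecord],
                 revisions: Sequence[RevisionRecord],
                 vitals: Sequence[VitalRecord],
                 inclusion_window: tuple[date, date],
                 horizon_days: int = 365) -> Cohort:
    """Merge, exclude, and attach follow-up windows in one call."""
    merged = merge_sources(arthro, fracture)
    cohort = apply_exclusions(merged, inclusion_window)
    rev_by_patient: dict[str, list[RevisionRecord]] = {}
    for r in revisions:
        rev_by_patient.setdefault(r.patient_id, []).append(r)
    vit_by_patient: dict[str, list[VitalRecord]] = {}
    for v in vitals:
        vit_by_patient.setdefault(v.patient_id, []).append(v)
    cohort.members = [
        (t, compute_followup(t, rev_by_patient.get(t.patient_id, ()),
                             vit_by_patient.get(t.patient_id, ()),
                             horizon_days))
        for t, _ in cohort.members
    ]
    return cohort


_COHORT_COLUMNS = ("patient_id", "side", "surgery_date", "diagnosis_group",
                   "hospital_id", "source", "followup_start", "followup_end",
                   "end_reason")


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort (THA fields plus follow-up window) as delimited text."""
    import csv
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_COHORT_COLUMNS)
        for t, win in cohort.members:
            w.writerow([t.patient_id, t.side.value, t.surgery_date.isoformat(),
                        t.diagnosis_group.value, t.hospital_id, t.source.value,
                        win.start.isoformat(), win.end.isoformat(),
                        win.end_reason.value])


def read_cohort(path, inclusion_window: Optional[tuple[date, date]] = None
                ) -> Cohort:
    """Read a cohort file; the inclusion window, if not given, is taken as
    the span of observed surgery dates."""
    import csv
    from pathlib import Path

    from .registry_model import DiagnosisGroup, SchemaError

    path = Path(path)
    members = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != _COHORT_COLUMNS:
            raise SchemaError(f"{path}: expected columns {_COHORT_COLUMNS}")
        for row in reader:
            t = ThaRecord(
                patient_id=row["patient_id"], side=Side(row["side"]),
                surgery_date=date.fromisoformat(row["surgery_date"]),
                diagnosis_group=DiagnosisGroup(row["diagnosis_group"]),
                hospital_id=row["hospital_id"], source=Source(row["source"]))
            win = FollowUpWindow(
                start=date.fromisoformat(row["followup_start"]),
                end=date.fromisoformat(row["followup_end"]),
                end_reason=EndReason(row["end_reason"]))
            members.append((t, win))
    if inclusion_window is None:
        dates = [t.surgery_date for t, _ in members] or [date.today()]
        inclusion_window = (min(dates), max(dates))
    return Cohort(members=members, inclusion_window=inclusion_window)
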