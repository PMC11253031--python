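"""Reconstruct distinct dislocation events from contact-level data.

Administrative contact streams over-count events (a hospital transfer opens
a new contact for the same dislocation) and under-count them (one admission
may include two reductions).  This module collapses transfer duplicates and
expands multi-reduction admissions:

* contacts sharing an admission link id belong to one clinical course;
* a qualifying contact starting within ``gap_days`` of another qualifying
  contact of the same patient and side at a *different* hospital is treated
  as a transfer duplicate;
* two qualifying contacts for one patient on the same day at the same
  hospital are one event (duplicate registration) unless the admission's
  dislocation count says otherwise;
* each merged group yields ``max(n_dislocations_in_admission)`` events
  (minimum 1) dated at the group's earliest contact start.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Mapping, Optional, Sequence

from .registry_model import (
    DataError,
    HospitalContact,
    Laterality,
    ProportionEstimate,
    Side,
)
from .validation_metrics import proportion_estimate

__all__ = ["LinkedEvent", "RecurrenceSummary", "collapse_events",
           "recurrence_summary"]


@dataclass(frozen=True, slots=True)
class LinkedEvent:
    """One reconstructed dislocation event with its source contacts."""

    patient_id: str
    side: Optional[Side]
    event_date: date
    source_contact_ids: tuple[str, ...]
    admission_link_id: str


def _contact_side(contact: HospitalContact) -> Optional[Side]:
    """The unique known laterality among the contact's codes, if any."""
    sides = {e.laterality
             for e in list(contact.diagnosis_codes) + list(contact.procedure_codes)
             if e.laterality is not Laterality.UNKNOWN}
    if len(sides) == 1:
        return Side(next(iter(sides)).value)
    return None


def _sides_compatible(a: Optional[Side], b: Optional[Side]) -> bool:
    return a is None or b is None or a == b


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def collapse_events(dislocation_contacts: Sequence[HospitalContact],
                    gap_days: int = 1,
                    index_sides: Optional[Mapping[str, Side]] = None
                    ) -> list[LinkedEvent]:
    """Merge qualifying contacts into events.

    ``dislocation_contacts`` are contacts already known to carry a
    dislocation — either annotated with ``n_dislocations_in_admission >= 1``
    (the gold channel of synthetic data) or flagged by the classifier (the
    code channel, where the count defaults to 1).

    ``index_sides`` optionally maps patient id to the index-hip side; when
    given it overrides side inference from code laterality (in a cohort
    with contralateral THAs excluded, every relevant event concerns the
    index hip).  Contacts of different patients sharing one admission link
    id raise :class:`DataError`.
    """
    contacts = sorted(dislocation_contacts,
                      key=lambda c: (c.patient_id, c.start_date, c.contact_id))
    by_admission: dict[str, str] = {}
    for c in contacts:
        if c.admission_link_id:
            prev = by_admission.setdefault(c.admission_link_id, c.patient_id)
            if prev != c.patient_id:
                raise DataError(
                    f"admission {c.admission_link_id} spans patients "
                    f"{prev} and {c.patient_id}")

    uf = _UnionFind(len(contacts))
    sides = [_contact_side(c) for c in contacts]
    admission_first: dict[str, int] = {}
    for i, c in enumerate(contacts):
        if c.admission_link_id:
            j = admission_first.setdefault(c.admission_link_id, i)
            uf.union(i, j)
        # contacts are patient/date sorted, so candidate partners are nearby
        for j in range(i + 1, len(contacts)):
            other = contacts[j]
            if other.patient_id != c.patient_id:
                break
            gap = (other.start_date - c.start_date).days
            if gap > gap_days:
                break
            if not _sides_compatible(sides[i], sides[j]):
                continue
            same_day_same_hospital = (gap == 0
                                      and other.hospital_id == c.hospital_id)
            transfer = other.hospital_id != c.hospital_id
            if transfer or same_day_same_hospital:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(contacts)):
        groups.setdefault(uf.find(i), []).append(i)

    events: list[LinkedEvent] = []
    for root in sorted(groups):
        members = groups[root]
        group = [contacts[i] for i in members]
        n_events = max(1, max(c.n_dislocations_in_admission for c in group))
        first_date = min(c.start_date for c in group)
        pid = group[0].patient_id
        if index_sides is not None and pid in index_sides:
            side = index_sides[pid]
        else:
            known = {s for i in members if (s := sides[i]) is not None}
            side = next(iter(known)) if len(known) == 1 else None
        link = next((c.admission_link_id for c in group if c.admission_link_id),
                    group[0].contact_id)
        source_ids = tuple(sorted(c.contact_id for c in group))
        for _ in range(n_events):
            events.append(LinkedEvent(
                patient_id=pid, side=side, event_date=first_date,
                source_contact_ids=source_ids, admission_link_id=link))
    events.sort(key=lambda e: (e.patient_id, e.event_date, e.admission_link_id))
    return events


@dataclass(frozen=True)
class RecurrenceSummary:
    """Per-patient event counts and the recurrence proportion.

    ``recurrence`` is the share of patients with >= 2 events among patients
    with >= 1 event; it is ``None`` (not 0) when no patient has any event.
    """

    events_per_patient: dict[str, int]
    n_patients: int
    n_events: int
    recurrence: Optional[ProportionEstimate]


def recurrence_summary(events: Sequence[LinkedEvent]) -> RecurrenceSummary:
    """Summarise linked events into recurrence statistics with an exact CI."""
    counts: dict[str, int] = {}
    for e in events:
        counts[e.patient_id] = counts.get(e.patient_id, 0) + 1
    n_patients = len(counts)
    n_events = sum(counts.values())
    recurrence = None
    if n_patients:
        recurrent = sum(1 for v in counts.values() if v >= 2)
        recurrence = proportion_estimate(recurrent, n_patients)
    return RecurrenceSummary(
        events_per_patient=dict(sorted(counts.items())),
        n_patients=n_patients, n_events=n_events, recurrence=recurrence)


_EVENT_COLUMNS = ("patient_id", "side", "event_date", "admission_link_id",
                  "source_contact_ids")


def write_events(events: Sequence[LinkedEvent], path) -> None:
    import csv
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_EVENT_COLUMNS)
        for e in events:
            w.writerow([e.patient_id,
                        e.side.value if e.side is not None else "unknown",
                        e.event_date.isoformat(), e.admission_link_id,
                        ";".join(e.source_contact_ids)])
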