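"""Event linking: how transfer duplicates collapse and multi-reduction
admissions expand when contacts are turned into distinct dislocation events.
"""

from datetime import date

from thadisloc import CodedEntry, HospitalContact, Laterality, Side
from thadisloc.event_linker import collapse_events, recurrence_summary

codes = dict(diagnosis_codes=[CodedEntry("DT84.0A", Laterality.RIGHT)],
             procedure_codes=[CodedEntry("KNFH20", Laterality.RIGHT)])

contacts = [
    # one dislocation admitted at h01, transferred next day to h02
    HospitalContact("c1", "patient-A", date(2019, 9, 10), "h01", "adm-1",
                    n_dislocations_in_admission=1, **codes),
    HospitalContact("c2", "patient-A", date(2019, 9, 11), "h02", "adm-1",
                    n_dislocations_in_admission=1, **codes),
    # a later admission in which the hip was reduced twice
    HospitalContact("c3", "patient-A", date(2019, 11, 2), "h01", "adm-2",
                    n_dislocations_in_admission=2, **codes),
    # an unrelated patient with a single dislocation
    HospitalContact("c4", "patient-B", date(2019, 8, 1), "h03", "adm-3",
                    n_dislocations_in_admission=1, **codes),
]

events = collapse_events(contacts, gap_days=1,
                         index_sides={"patient-A": Side.RIGHT,
                                      "patient-B": Side.RIGHT})
print(f"{len(contacts)} contacts -> {len(events)} events")
for e in events:
    print(f"  {e.patient_id} {e.side.value} {e.event_date} "
          f"(admission {e.admission_link_id}, from {e.source_contact_ids})")

summary = recurrence_summary(events)
print(f"\nevents per patient: {summary.events_per_patient}")
print(f"recurrence: {summary.recurrence} "
      f"({summary.recurrence.k} of {summary.recurrence.n} dislocating "
      "patients had more than one event)")
print("\nReading: the transfer pair c1+c2 collapses to one event, while the "
      "two-reduction admission c3 expands to two — 4 contacts yield 4 "
      "events across 2 patients.")
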