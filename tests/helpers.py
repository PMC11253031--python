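"""Shared builders for hand-constructed registry objects."""

from __future__ import annotations

from datetime import date, timedelta

from thadisloc import (
    CodedEntry,
    DiagnosisGroup,
    FollowUpWindow,
    HospitalContact,
    Laterality,
    Side,
    Source,
    ThaRecord,
)


def make_tha(pid="p1", side=Side.RIGHT, day=0, group=DiagnosisGroup.PRIMARY_OA,
             hospital="h01", source=Source.ARTHROPLASTY_REGISTER,
             start=date(2019, 7, 1)) -> ThaRecord:
    return ThaRecord(patient_id=pid, side=side,
                     surgery_date=start + timedelta(days=day),
                     diagnosis_group=group, hospital_id=hospital,
                     source=source)


def make_window(tha: ThaRecord, days=365) -> FollowUpWindow:
    return FollowUpWindow(tha.surgery_date,
                          tha.surgery_date + timedelta(days=days))


def make_contact(pid="p1", day=30, codes=(), procs=(), contact_id="c1",
                 hospital="h01", admission="a1", n_disloc=0,
                 start=date(2019, 7, 1)) -> HospitalContact:
    """codes/procs are (code, side) pairs; side may be a Laterality, a Side,
    or the string 'unknown'."""

    def entry(item):
        code, lat = item
        if isinstance(lat, Side):
            lat = Laterality(lat.value)
        elif isinstance(lat, str):
            lat = Laterality(lat)
        return CodedEntry(code, lat)

    return HospitalContact(
        contact_id=contact_id, patient_id=pid,
        start_date=start + timedelta(days=day), hospital_id=hospital,
        admission_link_id=admission,
        diagnosis_codes=[entry(i) for i in codes],
        procedure_codes=[entry(i) for i in procs],
        n_dislocations_in_admission=n_disloc)
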