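"""Synthetic registry generator.

Produces a complete, internally consistent registry bundle — THAs,
post-operative hospital contacts, revisions, vital records and a
gold-standard dislocation event table — with the statistical structure the
validation analysis assumes, so that every pipeline stage is testable
without access to person-identifiable register data.

The generator emulates, with configurable parameters:

* a national 6-month cohort of primary THAs across ~42 hospitals of very
  unequal volume, with the published diagnosis mix;
* per-diagnosis 1-year risk of a first dislocation, modulated by a mean-one
  multiplicative hospital effect;
* recurrent dislocations as a truncated geometric process (continuation
  probability 0.37, at most 5 events), which simultaneously reproduces a
  37% recurrence share and ~1.6 events per dislocating patient;
* censoring by revision, death and emigration, including late revisions
  *caused by* dislocation (placed after the patient's last event);
* a coding-behaviour model: each patient's dislocation contacts are coded
  so that they are first captured at algorithm stage 1, 2, 3 or 4 — or
  never — with probabilities derived from the published cumulative stage
  capture; the capture stage is drawn once per patient, because coding
  style is a property of the treating pathway and the validation counts
  are patient-level;
* transfer-duplicate contacts sharing the admission link id, admissions
  with two reductions, a background of non-dislocation noise contacts, and
  rare false-positive contacts that genuinely qualify at configured stages.

All sampling is drawn from a single seeded NumPy generator in a fixed,
documented order, so identical (params, seed) yield byte-identical bundles.
"""

from __future__ import annotations

import math
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .registry_model import (
    CodedEntry,
    DiagnosisGroup,
    EndReason,
    FollowUpWindow,
    GoldEvent,
    HospitalContact,
    Laterality,
    Reduction,
    RegistryBundle,
    RevisionCause,
    RevisionRecord,
    Side,
    Source,
    ThaRecord,
    VitalRecord,
)

__all__ = [
    "SimParams",
    "default_params",
    "generate_registry",
    "sample_event_history",
    "encode_event",
    "generate_noise_contacts",
]

_PROB_TOL = 1e-9

# Published calibration counts (diagnosis mix and dislocators per group,
# cumulative patients captured per stage, contact partition).
_GROUP_COUNTS = {
    DiagnosisGroup.PRIMARY_OA: (4472, 113),
    DiagnosisGroup.ACUTE_FNF: (269, 12),
    DiagnosisGroup.FRACTURE_SEQUELAE: (226, 12),
    DiagnosisGroup.DYSPLASIA: (155, 3),
    DiagnosisGroup.FEMORAL_HEAD_NECROSIS: (104, 4),
    DiagnosisGroup.OTHER: (189, 8),
}
_COHORT_N = 5415
_DISLOCATORS = 152
_STAGE_CAPTURED = (79, 106, 135, 144)  # cumulative patients per stage
_EVENT_CONTACTS = 240
_TRANSFER_CONTACTS = 131
_MULTI_EVENT_ADMISSIONS = 3  # 243 events across 240 event-bearing contacts
_TOTAL_EVENTS = 243
_OPEN_REDUCTIONS = 2
_FP_PATIENTS_BY_STAGE = (0, 2, 6, 10)  # cumulative false-positive patients
_NOISE_CONTACTS = 1370

_REASON_ORDER = {EndReason.REVISION: 0, EndReason.DEATH: 1,
                 EndReason.MIGRATION: 2, EndReason.HORIZON: 3}


class EventTimeModel(BaseModel):
    """First-event time: Weibull (days), truncated to the follow-up horizon.

    The default shape < 1 makes early dislocations most likely, consistent
    with the large share of first-year events in two-year series.
    """

    model_config = ConfigDict(frozen=True)
    shape: float = Field(0.7, gt=0)
    scale_days: float = Field(200.0, gt=0)


class RepeatGapModel(BaseModel):
    """Gap between admissions of successive events: shifted exponential."""

    model_config = ConfigDict(frozen=True)
    mean_days: float = Field(30.0, gt=0)
    min_days: int = Field(4, ge=2)  # keeps separate admissions apart for linking


class SimParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    cohort_n: int = Field(_COHORT_N, ge=0)
    inclusion_window: tuple[date, date] = (date(2019, 7, 1), date(2019, 12, 31))
    horizon_days: int = Field(365, ge=1)
    diagnosis_mix: dict[DiagnosisGroup, float]
    incidence_1yr: dict[DiagnosisGroup, float]
    recurrence_continuation: float = Field(0.37, ge=0, le=1)
    max_events: int = Field(5, ge=1)
    event_time_model: EventTimeModel = EventTimeModel()
    repeat_gap_model: RepeatGapModel = RepeatGapModel()
    #: P(first captured at stage 1..4, never captured); drawn once per patient.
    coding_increments: tuple[float, float, float, float, float]
    #: expected stage-qualifying false-positive contacts per patient-year
    fp_contact_rate: float = Field(ge=0)
    #: split of false-positive contacts over minimal qualifying stage 1..4
    fp_stage_split: tuple[float, float, float, float] = (0.0, 0.2, 0.4, 0.4)
    #: expected non-qualifying contacts per patient-year
    noise_contact_rate: float = Field(ge=0)
    transfer_prob: float = Field(ge=0, le=1)
    multi_dislocation_prob: float = Field(ge=0, le=1)
    open_reduction_prob: float = Field(ge=0, le=1)
    death_rate_1yr: float = Field(0.025, ge=0, le=1)
    revision_other_rate_1yr: float = Field(0.018, ge=0, le=1)
    revision_dislocation_rate_1yr: float = Field(0.007, ge=0, le=1)
    migration_rate_1yr: float = Field(0.002, ge=0, le=1)
    hospital_count: int = Field(42, ge=1)
    #: sd of the log of the mean-one multiplicative hospital risk effect
    hospital_effect_sd: float = Field(0.45, ge=0)
    #: sd of the log hospital-volume weights (unequal hospital sizes)
    hospital_volume_sd: float = Field(1.0, ge=0)
    #: share of patients with a pre-existing contralateral THA (before the
    #: inclusion window), exercising laterality handling and exclusions
    prior_contralateral_prob: float = Field(0.10, ge=0, le=1)
    #: share of acute-fracture THAs recorded only in the hip-fracture
    #: register (missing from the arthroplasty register)
    fracture_register_only_prob: float = Field(0.25, ge=0, le=1)

    @field_validator("diagnosis_mix")
    @classmethod
    def _mix_sums_to_one(cls, v):
        total = sum(v.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"diagnosis_mix sums to {total}, expected 1")
        if any(p < 0 for p in v.values()):
            raise ValueError("diagnosis_mix entries must be >= 0")
        return v

    @field_validator("incidence_1yr")
    @classmethod
    def _incidence_in_unit(cls, v):
        if any(not 0 <= p <= 1 for p in v.values()):
            raise ValueError("incidence_1yr entries must be in [0, 1]")
        return v

    @field_validator("coding_increments")
    @classmethod
    def _increments_sum_to_one(cls, v):
        if abs(sum(v) - 1.0) > _PROB_TOL or any(p < 0 for p in v):
            raise ValueError("coding_increments must be >= 0 and sum to 1 "
                             "(including the never-captured mass)")
        return v

    @field_validator("fp_stage_split")
    @classmethod
    def _split_sums_to_one(cls, v):
        if abs(sum(v) - 1.0) > _PROB_TOL or any(p < 0 for p in v):
            raise ValueError("fp_stage_split must be >= 0 and sum to 1")
        return v

    @model_validator(mode="after")
    def _window_ordered(self):
        if self.inclusion_window[0] > self.inclusion_window[1]:
            raise ValueError("inclusion window start after end")
        return self

    @property
    def overall_incidence(self) -> float:
        return sum(self.diagnosis_mix[g] * self.incidence_1yr[g]
                   for g in self.diagnosis_mix)


def default_params(**overrides) -> SimParams:
    """Parameters calibrated to the published national 2019 cohort.

    Diagnosis mix and per-group 1-year dislocation risks come from the
    published per-group patient and dislocator counts (4,472/269/226/155/
    104/189 patients; 113/12/12/3/4/8 dislocators out of 5,415).  The
    per-patient capture-stage distribution is the differenced cumulative
    stage capture 79/106/135/144 of 152, leaving 8/152 never captured.
    Transfer and multi-reduction probabilities follow the published contact
    partition (240 event-bearing contacts, 131 transfer duplicates, 243
    events), the false-positive rate the 10/5,415 stage-4 false positives,
    and the noise rate the 1,370 reviewed non-dislocation contacts.
    """
    mix = {g: n / _COHORT_N for g, (n, _) in _GROUP_COUNTS.items()}
    incidence = {g: k / n for g, (n, k) in _GROUP_COUNTS.items()}
    captured = _STAGE_CAPTURED
    increments = (
        captured[0] / _DISLOCATORS,
        (captured[1] - captured[0]) / _DISLOCATORS,
        (captured[2] - captured[1]) / _DISLOCATORS,
        (captured[3] - captured[2]) / _DISLOCATORS,
        (_DISLOCATORS - captured[3]) / _DISLOCATORS,
    )
    fp_total = _FP_PATIENTS_BY_STAGE[-1]
    split_counts = (
        _FP_PATIENTS_BY_STAGE[0],
        _FP_PATIENTS_BY_STAGE[1] - _FP_PATIENTS_BY_STAGE[0],
        _FP_PATIENTS_BY_STAGE[2] - _FP_PATIENTS_BY_STAGE[1],
        _FP_PATIENTS_BY_STAGE[3] - _FP_PATIENTS_BY_STAGE[2],
    )
    base = dict(
        diagnosis_mix=mix,
        incidence_1yr=incidence,
        coding_increments=increments,
        fp_contact_rate=fp_total / _COHORT_N,
        fp_stage_split=tuple(c / fp_total for c in split_counts),
        noise_contact_rate=_NOISE_CONTACTS / _COHORT_N,
        transfer_prob=_TRANSFER_CONTACTS / _EVENT_CONTACTS,
        multi_dislocation_prob=_MULTI_EVENT_ADMISSIONS / _EVENT_CONTACTS,
        open_reduction_prob=_OPEN_REDUCTIONS / _TOTAL_EVENTS,
    )
    base.update(overrides)
    return SimParams(**base)


# ---------------------------------------------------------------------------
# Code realisation
# ---------------------------------------------------------------------------

_NOISE_DX_POOL = ("DM16.1", "DZ47.8", "DS82.1", "DI21.9", "DJ18.9",
                  "DS00.8", "DN39.0", "DK57.9")


def _lat(side: Optional[Side]) -> Laterality:
    return Laterality(side.value) if side is not None else Laterality.UNKNOWN


def _realize_stage_codes(stage: int, side: Side, rng: np.random.Generator,
                         reduction: Reduction = Reduction.CLOSED,
                         ) -> tuple[list[CodedEntry], list[CodedEntry]]:
    """Diagnosis/procedure codes whose *minimal* qualifying stage is ``stage``.

    Stage 0 denotes a never-captured (miscoded) dislocation contact: a lone
    dislocation-flavoured diagnosis with no reduction procedure, which no
    stage's pair rule matches.
    """
    proc_prosthesis = "KNFH22" if reduction is Reduction.OPEN else "KNFH20"
    proc_native = "KNFH02" if reduction is Reduction.OPEN else "KNFH00"
    s = _lat(side)
    if stage == 1:
        return [CodedEntry("DT84.0A", s)], [CodedEntry(proc_prosthesis, s)]
    if stage == 2:
        if rng.random() < 0.5:
            return [CodedEntry("DT84.0A", s)], [CodedEntry(proc_native, s)]
        return [CodedEntry("DS73.0", s)], [CodedEntry(proc_prosthesis, s)]
    if stage == 3:
        return [CodedEntry("DS73.0", s)], [CodedEntry(proc_native, s)]
    if stage == 4:
        dx = [CodedEntry("DT84.0A", Laterality.UNKNOWN)]
        # occasionally a second, contralateral injury code makes the
        # contact's laterality genuinely ambiguous
        if rng.random() < 0.3:
            other = Side.LEFT if side is Side.RIGHT else Side.RIGHT
            dx.append(CodedEntry("DS80.0", _lat(other)))
        return dx, [CodedEntry(proc_prosthesis, Laterality.UNKNOWN)]
    if stage == 0:
        code = "DT84.0A" if rng.random() < 0.5 else "DS73.0"
        return [CodedEntry(code, s)], []
    raise ValueError(f"no realisation for stage {stage}")


# ---------------------------------------------------------------------------
# Event histories
# ---------------------------------------------------------------------------


def _truncated_weibull_day(model: EventTimeModel, horizon_days: int,
                           rng: np.random.Generator) -> int:
    """A first-event day in [0, horizon], inverse-CDF of the truncated Weibull."""
    k, lam = model.shape, model.scale_days
    mass = 1.0 - math.exp(-((horizon_days / lam) ** k))
    u = rng.random() * mass
    t = lam * (-math.log(1.0 - u)) ** (1.0 / k)
    return min(int(t), horizon_days)


def _sample_admission_days(window_days: int, horizon_days: int,
                           params: SimParams, rng: np.random.Generator
                           ) -> list[list[int]]:
    """Event days for one dislocating patient, grouped by admission.

    The first event day is drawn from the truncated timing model; the
    patient is only *observed* to dislocate if it precedes the censoring
    date (``window_days``).  Each further event occurs with the recurrence
    continuation probability, capped at ``max_events``, and lands either in
    the same admission (two reductions in one course) or in a new admission
    after a shifted-exponential gap; events beyond the window are censored.
    """
    first = _truncated_weibull_day(params.event_time_model, horizon_days, rng)
    if first > window_days:
        return []
    admissions = [[first]]
    n_events = 1
    day = first
    while n_events < params.max_events:
        if rng.random() >= params.recurrence_continuation:
            break
        same_admission = (len(admissions[-1]) < 2
                          and rng.random() < params.multi_dislocation_prob)
        if same_admission:
            day = admissions[-1][0] + int(rng.integers(1, 4))
            if day > window_days:
                break
            admissions[-1].append(day)
        else:
            gap = params.repeat_gap_model.min_days + rng.exponential(
                params.repeat_gap_model.mean_days)
            day = day + int(gap)
            if day > window_days:
                break
            admissions.append([day])
        n_events += 1
    return admissions


def sample_event_history(tha: ThaRecord, window: FollowUpWindow,
                         params: SimParams, rng: np.random.Generator,
                         risk_multiplier: float = 1.0,
                         is_dislocator: Optional[bool] = None
                         ) -> list[GoldEvent]:
    """Sample the gold dislocation history of one THA inside its window.

    With probability ``incidence_1yr[group] * risk_multiplier`` the patient
    dislocates at least once (pass ``is_dislocator`` to supply this draw
    externally); recurrences follow the truncated geometric continuation.
    Admission link ids are local (``a1``, ``a2``, ...) unless the caller
    re-links the returned events.
    """
    if is_dislocator is None:
        p = min(1.0, params.incidence_1yr[tha.diagnosis_group] * risk_multiplier)
        is_dislocator = bool(rng.random() < p)
    if not is_dislocator or window.days < 0:
        return []
    admissions = _sample_admission_days(window.days, params.horizon_days,
                                        params, rng)
    events = []
    for i, days in enumerate(admissions, start=1):
        for d in days:
            reduction = (Reduction.OPEN
                         if rng.random() < params.open_reduction_prob
                         else Reduction.CLOSED)
            events.append(GoldEvent(
                patient_id=tha.patient_id, side=tha.side,
                event_date=window.start + timedelta(days=d),
                reduction=reduction, admission_link_id=f"a{i}"))
    return events


# ---------------------------------------------------------------------------
# Contact encoding
# ---------------------------------------------------------------------------


def encode_event(event: GoldEvent, params: SimParams,
                 rng: np.random.Generator, *, stage: Optional[int] = None,
                 n_in_admission: int = 1, hospital_id: str = "h01",
                 transfer_hospital_id: str = "h02",
                 contact_prefix: str = "c") -> list[HospitalContact]:
    """Emit the coded contact(s) an admission leaves in the register.

    ``stage`` is the stage at which the contact is first captured (0 =
    never; sampled from ``coding_increments`` when omitted — note the full
    generator samples it once per *patient*, not per event).  With
    probability ``transfer_prob`` a duplicate transfer contact at another
    hospital, sharing the admission link id, is appended.
    """
    if stage is None:
        stage = int(rng.choice([1, 2, 3, 4, 0],
                               p=list(params.coding_increments)))
    dx, proc = _realize_stage_codes(stage, event.side, rng, event.reduction)
    contacts = [HospitalContact(
        contact_id=f"{contact_prefix}1",
        patient_id=event.patient_id,
        start_date=event.event_date,
        hospital_id=hospital_id,
        admission_link_id=event.admission_link_id,
        diagnosis_codes=dx,
        procedure_codes=proc,
        n_dislocations_in_admission=n_in_admission,
    )]
    if rng.random() < params.transfer_prob:
        contacts.append(HospitalContact(
            contact_id=f"{contact_prefix}2",
            patient_id=event.patient_id,
            start_date=event.event_date + timedelta(days=1),
            hospital_id=transfer_hospital_id,
            admission_link_id=event.admission_link_id,
            diagnosis_codes=list(dx),
            procedure_codes=list(proc),
            n_dislocations_in_admission=n_in_admission,
        ))
    return contacts


def generate_noise_contacts(cohort: Sequence[tuple[ThaRecord, FollowUpWindow]],
                            params: SimParams, rng: np.random.Generator,
                            contact_start: int = 0,
                            admission_start: int = 0
                            ) -> list[HospitalContact]:
    """Background contacts: non-qualifying noise plus rare false positives.

    Noise contacts (Poisson at ``noise_contact_rate`` per patient-year)
    carry unrelated codes or *partial* dislocation coding (a dislocation
    diagnosis without a reduction procedure, or vice versa) and never
    satisfy a pair rule; their gold annotation is 0.  False-positive
    contacts (Poisson at ``fp_contact_rate``) genuinely qualify, with their
    minimal stage drawn from ``fp_stage_split`` and laterality matching the
    index hip (or unknown for stage 4).
    """
    out: list[HospitalContact] = []
    cid = contact_start
    aid = admission_start
    exposure = np.array([max(w.days, 0) / 365.0 for _, w in cohort])
    n_noise = rng.poisson(params.noise_contact_rate * exposure)
    n_fp = rng.poisson(params.fp_contact_rate * exposure)
    for (tha, window), k_noise, k_fp in zip(cohort, n_noise, n_fp):
        for _ in range(int(k_noise)):
            day = int(rng.integers(0, max(window.days, 0) + 1))
            u = rng.random()
            if u < 0.15:
                code = "DT84.0A" if rng.random() < 0.5 else "DS73.0"
                dx = [CodedEntry(code, _lat(tha.side))]
                proc = []
            elif u < 0.25:
                dx = [CodedEntry(str(rng.choice(_NOISE_DX_POOL)),
                                 Laterality.UNKNOWN)]
                proc = [CodedEntry("KNFH20", _lat(tha.side))]
            else:
                dx = [CodedEntry(str(rng.choice(_NOISE_DX_POOL)),
                                 Laterality.UNKNOWN)]
                proc = []
            cid += 1
            aid += 1
            out.append(HospitalContact(
                contact_id=f"c{cid:07d}", patient_id=tha.patient_id,
                start_date=window.start + timedelta(days=day),
                hospital_id=tha.hospital_id, admission_link_id=f"a{aid:07d}",
                diagnosis_codes=dx, procedure_codes=proc,
                n_dislocations_in_admission=0))
        for _ in range(int(k_fp)):
            day = int(rng.integers(0, max(window.days, 0) + 1))
            stage = 1 + int(rng.choice(4, p=list(params.fp_stage_split)))
            dx, proc = _realize_stage_codes(stage, tha.side, rng)
            cid += 1
            aid += 1
            out.append(HospitalContact(
                contact_id=f"c{cid:07d}", patient_id=tha.patient_id,
                start_date=window.start + timedelta(days=day),
                hospital_id=tha.hospital_id, admission_link_id=f"a{aid:07d}",
                diagnosis_codes=dx, procedure_codes=proc,
                n_dislocations_in_admission=0))
    return out


# ---------------------------------------------------------------------------
# Full bundle generation
# ---------------------------------------------------------------------------


def generate_registry(params: SimParams, seed: int) -> RegistryBundle:
    """Generate a full registry bundle; deterministic given (params, seed).

    Sampling order (one seeded stream): cohort-level vectors (surgery day,
    side, diagnosis group, hospital weights/effects/assignment, prior
    contralateral THAs, censoring draws, dislocator draws, per-patient
    capture stage), then per-dislocator event histories and contact
    encoding in patient order, then noise/false-positive contacts.
    """
    rng = np.random.default_rng(seed)
    n = params.cohort_n
    win_start, win_end = params.inclusion_window
    span = (win_end - win_start).days + 1
    groups = list(params.diagnosis_mix)

    surgery_offset = rng.integers(0, span, size=n)
    side_draw = rng.integers(0, 2, size=n)
    group_idx = rng.choice(len(groups), size=n,
                           p=[params.diagnosis_mix[g] for g in groups])
    volume_w = rng.lognormal(0.0, params.hospital_volume_sd,
                             size=params.hospital_count)
    volume_w /= volume_w.sum()
    hospital_idx = rng.choice(params.hospital_count, size=n, p=volume_w)
    # multiplicative risk effect per hospital, normalised to a patient-
    # weighted mean of one so the marginal incidence stays calibrated (a
    # handful of large hospitals would otherwise dominate the realised mean)
    hospital_effect = np.exp(rng.normal(0.0, params.hospital_effect_sd,
                                        size=params.hospital_count))
    if n > 0:
        assigned_mean = hospital_effect[hospital_idx].mean()
        if assigned_mean > 0:
            hospital_effect = hospital_effect / assigned_mean
    prior_contra = rng.random(n) < params.prior_contralateral_prob
    prior_offset = rng.integers(30, 5 * 365, size=n)
    fracture_only = rng.random(n) < params.fracture_register_only_prob

    death_u = rng.random(n)
    death_day = rng.integers(1, params.horizon_days + 1, size=n)
    revo_u = rng.random(n)
    revo_day = rng.integers(1, params.horizon_days + 1, size=n)
    migr_u = rng.random(n)
    migr_day = rng.integers(1, params.horizon_days + 1, size=n)

    risk = np.array([
        min(1.0, params.incidence_1yr[groups[g]] * hospital_effect[h])
        for g, h in zip(group_idx, hospital_idx)
    ])
    dislocator = rng.random(n) < risk
    capture_stage = rng.choice([1, 2, 3, 4, 0], size=n,
                               p=list(params.coding_increments))

    overall = params.overall_incidence
    p_rev_dx = (min(1.0, params.revision_dislocation_rate_1yr / overall)
                if overall > 0 else 0.0)

    thas: list[ThaRecord] = []
    prior_thas: list[ThaRecord] = []
    revisions: list[RevisionRecord] = []
    vitals: list[VitalRecord] = []
    gold_events: list[GoldEvent] = []
    contacts: list[HospitalContact] = []
    cohort_members: list[tuple[ThaRecord, FollowUpWindow]] = []
    contact_counter = 0
    admission_counter = 0

    for i in range(n):
        pid = f"p{i + 1:06d}"
        side = Side.LEFT if side_draw[i] == 0 else Side.RIGHT
        group = groups[group_idx[i]]
        hospital = f"h{hospital_idx[i] + 1:02d}"
        surgery = win_start + timedelta(days=int(surgery_offset[i]))
        source = (Source.FRACTURE_REGISTER
                  if group is DiagnosisGroup.ACUTE_FNF and fracture_only[i]
                  else Source.ARTHROPLASTY_REGISTER)
        tha = ThaRecord(patient_id=pid, side=side, surgery_date=surgery,
                        diagnosis_group=group, hospital_id=hospital,
                        source=source)
        thas.append(tha)
        if prior_contra[i]:
            other = Side.RIGHT if side is Side.LEFT else Side.LEFT
            prior_thas.append(ThaRecord(
                patient_id=pid, side=other,
                surgery_date=win_start - timedelta(days=int(prior_offset[i])),
                diagnosis_group=DiagnosisGroup.PRIMARY_OA,
                hospital_id=hospital, source=Source.ARTHROPLASTY_REGISTER))

        death = (int(death_day[i]) if death_u[i] < params.death_rate_1yr
                 else None)
        rev_other = (int(revo_day[i])
                     if revo_u[i] < params.revision_other_rate_1yr else None)
        migration = (int(migr_day[i])
                     if migr_u[i] < params.migration_rate_1yr else None)
        censor = min(d for d in (death, rev_other, migration,
                                 params.horizon_days) if d is not None)

        admissions: list[list[int]] = []
        if dislocator[i]:
            admissions = _sample_admission_days(censor, params.horizon_days,
                                                params, rng)
        rev_dx_day: Optional[int] = None
        if admissions and rng.random() < p_rev_dx:
            last = max(d for days in admissions for d in days)
            day = last + int(rng.integers(3, 31))
            if day <= censor and day <= params.horizon_days:
                rev_dx_day = day

        # end of follow-up: earliest candidate, ties broken like the
        # cohort builder (revision > death > migration > horizon)
        cands: list[tuple[int, EndReason]] = [
            (params.horizon_days, EndReason.HORIZON)]
        if rev_other is not None and rev_other <= censor:
            cands.append((rev_other, EndReason.REVISION))
        if rev_dx_day is not None:
            cands.append((rev_dx_day, EndReason.REVISION))
        if death is not None:
            cands.append((death, EndReason.DEATH))
        if migration is not None:
            cands.append((migration, EndReason.MIGRATION))
        end_day, end_reason = min(
            cands, key=lambda c: (c[0], _REASON_ORDER[c[1]]))
        window = FollowUpWindow(surgery, surgery + timedelta(days=end_day),
                                end_reason)

        if rev_other is not None and rev_other <= end_day:
            revisions.append(RevisionRecord(
                patient_id=pid, side=side,
                date=surgery + timedelta(days=rev_other),
                cause=RevisionCause.OTHER))
        if rev_dx_day is not None:
            revisions.append(RevisionRecord(
                patient_id=pid, side=side,
                date=surgery + timedelta(days=rev_dx_day),
                cause=RevisionCause.DISLOCATION))
        if death is not None or migration is not None:
            vitals.append(VitalRecord(
                patient_id=pid,
                death_date=(surgery + timedelta(days=death)
                            if death is not None else None),
                migration_date=(surgery + timedelta(days=migration)
                                if migration is not None else None)))

        stage = int(capture_stage[i])
        for days in admissions:
            admission_counter += 1
            link = f"a{admission_counter:07d}"
            admission_events = []
            for d in days:
                reduction = (Reduction.OPEN
                             if rng.random() < params.open_reduction_prob
                             else Reduction.CLOSED)
                admission_events.append(GoldEvent(
                    patient_id=pid, side=side,
                    event_date=surgery + timedelta(days=d),
                    reduction=reduction, admission_link_id=link))
            gold_events.extend(admission_events)
            lead = admission_events[0]
            transfer_hospital = f"h{int(rng.integers(1, params.hospital_count + 1)):02d}"
            encoded = encode_event(
                lead, params, rng, stage=stage,
                n_in_admission=len(admission_events),
                hospital_id=hospital,
                transfer_hospital_id=transfer_hospital,
                contact_prefix="x")
            for c in encoded:
                contact_counter += 1
                c.contact_id = f"c{contact_counter:07d}"
                contacts.append(c)

        cohort_members.append((tha, window))

    contacts.extend(generate_noise_contacts(
        cohort_members, params, rng,
        contact_start=contact_counter, admission_start=admission_counter))
    contacts.sort(key=lambda c: (c.patient_id, c.start_date, c.contact_id))

    all_thas = thas + prior_thas
    all_thas.sort(key=lambda t: (t.patient_id, t.side.value))
    return RegistryBundle(
        thas=all_thas,
        contacts=contacts,
        revisions=sorted(revisions, key=lambda r: (r.patient_id, r.date)),
        vitals=sorted(vitals, key=lambda v: v.patient_id),
        gold_events=sorted(gold_events,
                           key=lambda e: (e.patient_id, e.event_date)),
        provenance={"seed": seed,
                    "params": params.model_dump(mode="json")},
    )
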