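"""Generator: published-count calibration of defaults, determinism, and
the statistical structure of sampled histories and coded contacts."""

from __future__ import annotations

import filecmp
from datetime import date

import numpy as np
import pytest

from thadisloc import (
    DiagnosisGroup,
    FollowUpWindow,
    Laterality,
    default_params,
    encode_event,
    generate_noise_contacts,
    generate_registry,
    sample_event_history,
)
from thadisloc.dislocation_algorithm import compile_stages, match_contact
from thadisloc.registry_model import GoldEvent, Side, bundle_to_dir

from helpers import make_tha, make_window


class TestDefaultParams:
    def test_diagnosis_mix_follows_published_group_sizes(self):
        p = default_params()
        assert p.diagnosis_mix[DiagnosisGroup.PRIMARY_OA] == pytest.approx(
            4472 / 5415)
        assert sum(p.diagnosis_mix.values()) == pytest.approx(1.0)

    def test_group_incidences_follow_published_dislocator_counts(self):
        p = default_params()
        assert p.incidence_1yr[DiagnosisGroup.ACUTE_FNF] == pytest.approx(
            12 / 269)
        assert p.incidence_1yr[DiagnosisGroup.PRIMARY_OA] == pytest.approx(
            113 / 4472)
        assert p.overall_incidence == pytest.approx(152 / 5415)

    def test_coding_increments_are_differenced_cumulative_capture(self):
        # cumulative patient capture 79/106/135/144 of 152, differenced
        p = default_params()
        assert np.round(p.coding_increments, 3).tolist() == [
            0.520, 0.178, 0.191, 0.059, 0.053]
        assert sum(p.coding_increments) == pytest.approx(1.0)

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="coding_increments"):
            default_params(coding_increments=(0.5, 0.5, 0.5, 0.0, 0.0))


class TestGenerateRegistry:
    def test_zero_incidence_yields_no_gold_events(self):
        p = default_params(
            cohort_n=300,
            incidence_1yr={g: 0.0 for g in DiagnosisGroup})
        bundle = generate_registry(p, seed=3)
        assert bundle.gold_events == []

    def test_same_params_and_seed_give_byte_identical_bundles(self, tmp_path):
        p = default_params(cohort_n=300)
        for name in ("one", "two"):
            bundle_to_dir(generate_registry(p, seed=5), tmp_path / name)
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "one", tmp_path / "two",
            ["tha.csv", "contacts.csv", "revisions.csv", "vitals.csv",
             "gold_events.csv"], shallow=False)
        assert mismatch == [] and errors == []

    def test_annotated_contacts_map_to_gold_admissions(self, small_bundle):
        gold = {}
        for e in small_bundle.gold_events:
            key = (e.patient_id, e.admission_link_id)
            gold[key] = gold.get(key, 0) + 1
        for c in small_bundle.contacts:
            if c.n_dislocations_in_admission >= 1:
                assert gold[(c.patient_id, c.admission_link_id)] == \
                    c.n_dislocations_in_admission


class TestEventHistory:
    def test_expected_events_per_dislocator_matches_truncated_geometric(self):
        """Mean events per dislocating patient equals the closed form of the
        truncated geometric (independently enumerated here)."""
        q, cap = 0.37, 5
        pmf = [(1 - q) * q ** (k - 1) for k in range(1, cap)] + [q ** (cap - 1)]
        expected = sum(k * p for k, p in zip(range(1, cap + 1), pmf))
        assert expected == pytest.approx(1.5763, abs=1e-4)

        # horizon long enough that no recurrence is ever censored
        p = default_params(multi_dislocation_prob=0.0, horizon_days=20_000)
        rng = np.random.default_rng(42)
        tha = make_tha()
        window = make_window(tha, days=20_000)
        counts = [len(sample_event_history(tha, window, p, rng,
                                           is_dislocator=True))
                  for _ in range(4000)]
        assert np.mean(counts) == pytest.approx(expected, abs=0.05)
        assert max(counts) <= p.max_events

    def test_continuation_zero_gives_exactly_one_event(self):
        p = default_params(recurrence_continuation=0.0)
        rng = np.random.default_rng(0)
        tha = make_tha()
        for _ in range(50):
            events = sample_event_history(tha, make_window(tha), p, rng,
                                          is_dislocator=True)
            assert len(events) == 1

    def test_zero_length_window_admits_only_surgery_day_events(self):
        # the window is closed, so a same-day event counts; anything later
        # is censored out
        p = default_params()
        rng = np.random.default_rng(1)
        tha = make_tha()
        window = FollowUpWindow(tha.surgery_date, tha.surgery_date)
        for _ in range(200):
            for e in sample_event_history(tha, window, p, rng,
                                          is_dislocator=True):
                assert e.event_date == tha.surgery_date

    def test_all_event_dates_inside_window(self):
        p = default_params()
        rng = np.random.default_rng(9)
        tha = make_tha()
        window = FollowUpWindow(tha.surgery_date, make_window(tha, 90).end)
        for _ in range(300):
            for e in sample_event_history(tha, window, p, rng,
                                          is_dislocator=True):
                assert window.contains(e.event_date)


class TestEncodeEvent:
    def _event(self):
        return GoldEvent(patient_id="p1", side=Side.RIGHT,
                         event_date=date(2019, 9, 1), admission_link_id="a1")

    def test_stage1_contact_carries_correct_pair_with_event_side(self, rng):
        p = default_params(transfer_prob=0.0)
        contacts = encode_event(self._event(), p, rng, stage=1)
        (c,) = contacts
        assert any(e.code == "DT84.0A" and e.laterality is Laterality.RIGHT
                   for e in c.diagnosis_codes)
        assert any(e.code.startswith("KNFH2")
                   and e.laterality is Laterality.RIGHT
                   for e in c.procedure_codes)

    def test_missed_coding_qualifies_at_no_stage(self, rng):
        p = default_params(transfer_prob=0.0)
        cfg = compile_stages()
        tha = make_tha(side=Side.RIGHT, day=0)
        for _ in range(30):
            (c,) = encode_event(self._event(), p, rng, stage=0)
            assert match_contact(c, tha, cfg).stage is None

    @pytest.mark.parametrize("stage", [1, 2, 3, 4])
    def test_realised_minimal_stage_is_the_drawn_stage(self, stage, rng):
        p = default_params(transfer_prob=0.0)
        cfg = compile_stages()
        tha = make_tha(side=Side.RIGHT, day=0)
        for _ in range(25):
            (c,) = encode_event(self._event(), p, rng, stage=stage)
            assert match_contact(c, tha, cfg).stage == stage

    def test_sampled_capture_fraction_matches_increments(self, rng):
        """Per-event stage sampling: fraction captured at stage <= 1 within
        Monte-Carlo tolerance of the configured 0.52."""
        p = default_params(transfer_prob=0.0)
        cfg = compile_stages()
        tha = make_tha(side=Side.RIGHT, day=0)
        n = 10_000
        hits = 0
        for _ in range(n):
            (c,) = encode_event(self._event(), p, rng)
            if (m := match_contact(c, tha, cfg).stage) is not None and m <= 1:
                hits += 1
        p1 = 79 / 152
        assert abs(hits / n - p1) < 3 * np.sqrt(p1 * (1 - p1) / n)

    def test_transfer_duplicate_shares_admission_link(self, rng):
        p = default_params(transfer_prob=1.0)
        contacts = encode_event(self._event(), p, rng, stage=1,
                                hospital_id="h01", transfer_hospital_id="h07")
        assert len(contacts) == 2
        assert contacts[0].admission_link_id == contacts[1].admission_link_id
        assert contacts[0].hospital_id != contacts[1].hospital_id


class TestNoiseContacts:
    def test_zero_rates_give_empty_list(self, rng):
        p = default_params(noise_contact_rate=0.0, fp_contact_rate=0.0)
        tha = make_tha()
        out = generate_noise_contacts([(tha, make_window(tha))], p, rng)
        assert out == []

    def test_noise_contacts_have_zero_annotation_and_never_qualify(self, rng):
        p = default_params(fp_contact_rate=0.0, noise_contact_rate=40.0)
        cfg = compile_stages()
        tha = make_tha(side=Side.LEFT)
        out = generate_noise_contacts([(tha, make_window(tha))], p, rng)
        assert len(out) > 0
        for c in out:
            assert c.n_dislocations_in_admission == 0
            assert match_contact(c, tha, cfg).stage is None

    def test_false_positive_stage4_patient_fraction_calibrated(self):
        """At n=40,000 the stage-4 false-positive patient fraction is within
        Monte-Carlo tolerance of the published 10/5,415."""
        p = default_params(cohort_n=40_000)
        bundle = generate_registry(p, seed=13)
        cfg = compile_stages()
        lo, hi = p.inclusion_window
        tha_by_pid = {t.patient_id: t for t in bundle.thas
                      if lo <= t.surgery_date <= hi}
        gold = {e.patient_id for e in bundle.gold_events}
        fp_patients = set()
        for c in bundle.contacts:
            if c.patient_id in gold or c.n_dislocations_in_admission:
                continue
            if match_contact(c, tha_by_pid[c.patient_id], cfg).stage is not None:
                fp_patients.add(c.patient_id)
        n_neg = len(set(tha_by_pid) - gold)
        target = 10 / 5415
        se = np.sqrt(target * (1 - target) / n_neg)
        assert abs(len(fp_patients) / n_neg - target) < 3 * se
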