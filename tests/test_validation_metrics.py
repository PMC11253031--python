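"""Exact binomial intervals, 2x2 construction, diagnostic metrics,
incidence tables, hospital ranges, and the combined report."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from thadisloc import (
    Cohort,
    PatientFlag,
    TwoByTwo,
    build_report,
    clopper_pearson,
    confusion,
    diagnostic_metrics,
    hospital_incidence_range,
    incidence_by_group,
    proportion_estimate,
)
from thadisloc.registry_model import DataError
from thadisloc.validation_metrics import round_half_up

from helpers import make_tha, make_window

WINDOW = (date(2019, 7, 1), date(2019, 12, 31))


def _cohort_of(thas):
    return Cohort(members=[(t, make_window(t)) for t in thas],
                  inclusion_window=WINDOW)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n,low,high", [
        (4, 104, 1.1, 9.6),      # femoral head necrosis row
        (152, 5415, 2.4, 3.3),   # overall 1-year incidence
        (3, 155, 0.4, 5.6),      # hip dysplasia row
        (12, 269, 2.3, 7.7),     # acute femoral neck fracture row
        (12, 226, 2.8, 9.1),     # fracture sequelae row
        (113, 4472, 2.1, 3.0),   # primary osteoarthritis row
        (8, 189, 1.8, 8.2),      # other diagnoses row
    ])
    def test_register_table_intervals_reproduce_at_one_decimal(
            self, k, n, low, high):
        lo, hi = clopper_pearson(k, n)
        assert round_half_up(lo) == low
        assert round_half_up(hi) == high

    def test_boundaries_pin_to_zero_and_hundred(self):
        assert clopper_pearson(0, 50)[0] == 0.0
        assert clopper_pearson(50, 50)[1] == 100.0

    def test_undefined_for_empty_denominator(self):
        with pytest.raises(DataError):
            clopper_pearson(0, 0)

    def test_coverage_is_at_least_nominal(self):
        """Across 2,000 simulated binomial draws at several (n, p), the
        exact interval covers the true p at >= 95% (the method is
        conservative by construction)."""
        rng = np.random.default_rng(7)
        n_sim = 2000
        for n, p in [(20, 0.1), (50, 0.5), (200, 0.028), (152, 0.37)]:
            ks = rng.binomial(n, p, size=n_sim)
            alpha = 0.05
            lows = np.where(ks == 0, 0.0,
                            beta_dist.ppf(alpha / 2, ks, n - ks + 1))
            highs = np.where(ks == n, 1.0,
                             beta_dist.ppf(1 - alpha / 2, ks + 1, n - ks))
            coverage = np.mean((lows <= p) & (p <= highs))
            assert coverage >= 0.95

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(min_value=1, max_value=10_000), st.data())
    def test_interval_brackets_point_and_orders_with_k(self, n, data):
        """For any k <= n the interval brackets k/n within [0, 100], and
        both bounds are non-decreasing in k at fixed n."""
        k = data.draw(st.integers(min_value=0, max_value=n))
        lo, hi = clopper_pearson(k, n)
        point = 100 * k / n
        assert 0.0 <= lo <= point <= hi <= 100.0
        if k < n:
            lo2, hi2 = clopper_pearson(k + 1, n)
            assert lo2 >= lo and hi2 >= hi

    def test_rounding_is_half_up(self):
        assert round_half_up(2.85) == 2.9
        assert round_half_up(43.74, 0) == 44
        assert round_half_up(94.74, 0) == 95


class TestConfusion:
    def _flags(self, flagged_ids, cohort):
        return [PatientFlag(t.patient_id, t.patient_id in flagged_ids)
                for t, _ in cohort.members]

    def test_hand_counted_two_by_two(self):
        cohort = _cohort_of([make_tha(pid=p) for p in "ABCD"])
        tb = confusion(cohort, {"A", "B"}, self._flags({"B", "C"}, cohort))
        assert (tb.tp, tb.fp, tb.fn, tb.tn) == (1, 1, 1, 1)

    def test_perfect_agreement_has_no_errors(self):
        cohort = _cohort_of([make_tha(pid=f"p{i}") for i in range(6)])
        tb = confusion(cohort, {"p0", "p1"}, self._flags({"p0", "p1"}, cohort))
        assert tb.fp == tb.fn == 0

    def test_flag_outside_cohort_is_an_error(self):
        cohort = _cohort_of([make_tha(pid="p0")])
        flags = [PatientFlag("p0", False), PatientFlag("intruder", True)]
        with pytest.raises(DataError, match="intruder"):
            confusion(cohort, set(), flags)

    def test_random_sets_match_set_arithmetic_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            cohort = _cohort_of([make_tha(pid=f"p{i}") for i in range(n)])
            ids = [f"p{i}" for i in range(n)]
            gold = {i for i in ids if rng.random() < 0.3}
            flagged = {i for i in ids if rng.random() < 0.4}
            tb = confusion(cohort, gold, self._flags(flagged, cohort))
            assert tb.tp == len(gold & flagged)
            assert tb.fp == len(flagged - gold)
            assert tb.fn == len(gold - flagged)
            assert tb.total == n


class TestDiagnosticMetrics:
    def test_stage_one_counts_give_52_percent_sensitivity(self):
        m = diagnostic_metrics(TwoByTwo(tp=79, fp=0, fn=73, tn=5263), stage=1)
        assert m.sensitivity.point_pct == 52.0
        assert round_half_up(m.sensitivity.ci_low_pct, 0) == 44
        assert round_half_up(m.sensitivity.ci_high_pct, 0) == 60
        assert m.ppv.point_pct == 100.0  # no false positives at stage 1

    def test_stage_four_counts(self):
        m = diagnostic_metrics(TwoByTwo(tp=144, fp=10, fn=8, tn=5253), stage=4)
        assert m.sensitivity.point_pct == 94.7
        assert m.specificity.point_pct == 99.8
        assert m.ppv.k == 144 and m.ppv.n == 154
        assert m.ppv.point_pct == 93.5

    def test_metric_with_zero_denominator_is_undefined(self):
        m = diagnostic_metrics(TwoByTwo(tp=0, fp=0, fn=0, tn=10))
        assert m.sensitivity is None and m.ppv is None
        assert m.specificity is not None

    def test_estimate_components_reconcile_with_table(self):
        tb = TwoByTwo(tp=135, fp=6, fn=17, tn=5257)
        m = diagnostic_metrics(tb)
        assert (m.sensitivity.k, m.sensitivity.n) == (tb.tp, tb.tp + tb.fn)
        assert (m.specificity.k, m.specificity.n) == (tb.tn, tb.tn + tb.fp)
        assert (m.npv.k, m.npv.n) == (tb.tn, tb.tn + tb.fn)


class TestIncidenceByGroup:
    def test_singleton_group_without_events_reports_zero_low(self):
        cohort = _cohort_of([make_tha(pid="p0")])
        table = incidence_by_group(cohort, set())
        assert table["primary_oa"].point_pct == 0.0
        assert table["primary_oa"].ci_low_pct == 0.0

    def test_overall_row_aggregates_all_groups(self, rng):
        thas = [make_tha(pid=f"p{i}") for i in range(40)]
        gold = {f"p{i}" for i in range(40) if rng.random() < 0.2}
        table = incidence_by_group(_cohort_of(thas), gold)
        assert table["overall"].k == len(gold)
        assert table["overall"].n == 40


class TestHospitalRange:
    def test_two_hospital_extremes(self):
        thas = ([make_tha(pid=f"a{i}", hospital="h1") for i in range(100)]
                + [make_tha(pid=f"b{i}", hospital="h2") for i in range(100)])
        gold = {"a0"} | {f"b{i}" for i in range(5)}
        result = hospital_incidence_range(_cohort_of(thas), gold, min_volume=1)
        assert result == (1.0, 5.0, 2)

    def test_min_volume_above_all_volumes_signals_empty(self):
        thas = [make_tha(pid="p0", hospital="h1")]
        assert hospital_incidence_range(_cohort_of(thas), set(),
                                        min_volume=100) is None

    def test_random_assignment_matches_brute_force(self, rng):
        for _ in range(20):
            thas = [make_tha(pid=f"p{i}",
                             hospital=f"h{int(rng.integers(1, 6))}")
                    for i in range(60)]
            gold = {t.patient_id for t in thas if rng.random() < 0.1}
            min_volume = int(rng.integers(1, 20))
            per_hosp = {}
            for t in thas:
                per_hosp.setdefault(t.hospital_id, []).append(
                    t.patient_id in gold)
            eligible = [100 * sum(v) / len(v) for v in per_hosp.values()
                        if len(v) >= min_volume]
            result = hospital_incidence_range(_cohort_of(thas), gold,
                                              min_volume)
            if not eligible:
                assert result is None
            else:
                assert result[0] == round_half_up(min(eligible))
                assert result[1] == round_half_up(max(eligible))
                assert result[2] == len(eligible)


class TestBuildReport:
    def _report(self):
        tables = {1: TwoByTwo(79, 0, 73, 5263), 2: TwoByTwo(106, 2, 46, 5261),
                  3: TwoByTwo(135, 6, 17, 5257), 4: TwoByTwo(144, 10, 8, 5253)}
        metrics = [diagnostic_metrics(tb, stage=s)
                   for s, tb in tables.items()]
        incidence = {g: proportion_estimate(k, n) for g, (n, k) in {
            "primary_oa": (4472, 113), "acute_fnf": (269, 12),
            "fracture_sequelae": (226, 12), "dysplasia": (155, 3),
            "femoral_head_necrosis": (104, 4), "other": (189, 8),
            "overall": (5415, 152)}.items()}
        return build_report(metrics, tables, incidence,
                            recurrence=proportion_estimate(56, 152),
                            hospital_range=(0.0, 9.6, 42),
                            hospital_range_min_volume=1)

    def test_structure_has_four_stages_and_six_plus_diagnosis_rows(self):
        report = self._report()
        data = report.to_json_dict()
        assert len(data["stages"]) == 4
        assert len([k for k in data["incidence"] if k != "overall"]) >= 6

    def test_stage_sensitivities_from_published_two_by_twos(self):
        data = self._report().to_json_dict()
        sens = [s["sensitivity"]["point_pct"] for s in data["stages"]]
        assert sens == [52.0, 69.7, 88.8, 94.7]

    def test_rendering_is_deterministic(self):
        a, b = self._report(), self._report()
        assert a.to_json() == b.to_json()
        assert a.to_text() == b.to_text()
        assert "52.0" in a.to_text()
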