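"""Diagnostic-accuracy statistics for the staged classifier.

Patient-level 2x2 tables per stage, sensitivity / specificity / PPV / NPV
with exact binomial confidence intervals, dislocation incidence by
diagnosis group and by hospital, and assembly of the combined validation
report.

The interval method is the Clopper-Pearson exact interval from beta
quantiles: for k successes in n trials at level 1 - alpha,

    lower = BetaInv(alpha/2;     k,     n - k + 1)   (0 when k = 0)
    upper = BetaInv(1 - alpha/2; k + 1, n - k)       (1 when k = n)

It is deliberately conservative (coverage >= the nominal level) and is the
method that reproduces small-count register tables exactly at one decimal.
Percentages are rounded half-up to one decimal throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from scipy.stats import beta as _beta

from .cohort_builder import Cohort
from .dislocation_algorithm import PatientFlag
from .registry_model import DataError, ProportionEstimate, TwoByTwo

__all__ = [
    "round_half_up",
    "clopper_pearson",
    "proportion_estimate",
    "confusion",
    "DiagnosticMetrics",
    "diagnostic_metrics",
    "incidence_by_group",
    "hospital_incidence_range",
    "ValidationReport",
    "build_report",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed tables do (2.85 -> 2.9)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial interval for k/n, as percentages (unrounded).

    Raises :class:`DataError` when n = 0 (the proportion is undefined).
    """
    if n < 1:
        raise DataError("proportion undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(_beta.ppf(1 - alpha / 2, k + 1, n - k))
    return 100.0 * low, 100.0 * high


def proportion_estimate(k: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """k/n as a :class:`ProportionEstimate` with exact CI, one-decimal percents."""
    low, high = clopper_pearson(k, n, level)
    return ProportionEstimate(
        k=k, n=n,
        point_pct=round_half_up(100.0 * k / n),
        ci_low_pct=round_half_up(low),
        ci_high_pct=round_half_up(high),
        method="clopper-pearson",
    )


def confusion(cohort: Cohort, gold_patients: set[str],
              flagged: Sequence[PatientFlag]) -> TwoByTwo:
    """Patient-level 2x2 of classifier flags against the reference standard."""
    cohort_ids = cohort.patient_ids
    flagged_ids = {f.patient_id for f in flagged if f.flagged}
    outside = flagged_ids - cohort_ids
    if outside:
        raise DataError(
            "flagged patient(s) outside cohort: " + ", ".join(sorted(outside)))
    gold = gold_patients & cohort_ids
    tp = len(gold & flagged_ids)
    fp = len(flagged_ids - gold)
    fn = len(gold - flagged_ids)
    tn = len(cohort_ids) - tp - fp - fn
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The four accuracy proportions of one stage; a metric whose
    denominator is zero is ``None`` (undefined), never 0 or 100."""

    stage: Optional[int]
    sensitivity: Optional[ProportionEstimate]
    specificity: Optional[ProportionEstimate]
    ppv: Optional[ProportionEstimate]
    npv: Optional[ProportionEstimate]


def diagnostic_metrics(tb: TwoByTwo, stage: Optional[int] = None,
                       level: float = 0.95) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV with exact CIs from one 2x2."""

    def safe(k: int, n: int) -> Optional[ProportionEstimate]:
        return proportion_estimate(k, n, level) if n > 0 else None

    return DiagnosticMetrics(
        stage=stage,
        sensitivity=safe(tb.tp, tb.tp + tb.fn),
        specificity=safe(tb.tn, tb.tn + tb.fp),
        ppv=safe(tb.tp, tb.tp + tb.fp),
        npv=safe(tb.tn, tb.tn + tb.fn),
    )


def incidence_by_group(cohort: Cohort, gold_patients: set[str],
                       grouping: str = "diagnosis_group",
                       level: float = 0.95) -> dict[str, ProportionEstimate]:
    """Dislocation incidence per level of a cohort attribute, plus overall.

    ``grouping`` names a :class:`ThaRecord` attribute (default the diagnosis
    group).  Keys are the attribute values (enum values as their strings),
    insertion-ordered by first appearance, with a final ``"overall"`` row.
    """
    table: dict[str, ProportionEstimate] = {}
    groups: dict[str, tuple[int, int]] = {}
    order: list[str] = []
    for tha, _ in cohort.members:
        value = getattr(tha, grouping)
        key = value.value if hasattr(value, "value") else str(value)
        n, k = groups.get(key, (0, 0))
        groups[key] = (n + 1, k + (tha.patient_id in gold_patients))
        if key not in order:
            order.append(key)
    for key in order:
        n, k = groups[key]
        table[key] = proportion_estimate(k, n, level)
    if cohort.members:
        total_n = len(cohort.members)
        total_k = sum(1 for t, _ in cohort.members
                      if t.patient_id in gold_patients)
        table["overall"] = proportion_estimate(total_k, total_n, level)
    return table


def hospital_incidence_range(
        cohort: Cohort, gold_patients: set[str],
        min_volume: int = 1) -> Optional[tuple[float, float, int]]:
    """Extremes of per-hospital incidence among hospitals with volume
    >= ``min_volume``; ``None`` when no hospital qualifies."""
    if min_volume < 1:
        raise ValueError("min_volume must be >= 1")
    volume: dict[str, int] = {}
    events: dict[str, int] = {}
    for tha, _ in cohort.members:
        volume[tha.hospital_id] = volume.get(tha.hospital_id, 0) + 1
        events[tha.hospital_id] = (events.get(tha.hospital_id, 0)
                                   + (tha.patient_id in gold_patients))
    incidences = [100.0 * events[h] / v
                  for h, v in volume.items() if v >= min_volume]
    if not incidences:
        return None
    return (round_half_up(min(incidences)), round_half_up(max(incidences)),
            len(incidences))


@dataclass
class ValidationReport:
    """The combined validation surface: per-stage accuracy, incidence by
    diagnosis, the 2x2 counts, recurrence, and hospital variation."""

    stage_metrics: list[DiagnosticMetrics]
    two_by_twos: dict[int, TwoByTwo]
    incidence: dict[str, ProportionEstimate]
    recurrence: Optional[ProportionEstimate] = None
    hospital_range: Optional[tuple[float, float, int]] = None
    hospital_range_min_volume: int = 1
    counts: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def prop(p: Optional[ProportionEstimate]):
            if p is None:
                return None
            return {"k": p.k, "n": p.n, "point_pct": p.point_pct,
                    "ci_low_pct": p.ci_low_pct, "ci_high_pct": p.ci_high_pct,
                    "method": p.method}

        return {
            "stages": [
                {
                    "stage": m.stage,
                    "two_by_two": (
                        {"tp": tb.tp, "fp": tb.fp, "fn": tb.fn, "tn": tb.tn}
                        if (tb := self.two_by_twos.get(m.stage)) else None),
                    "sensitivity": prop(m.sensitivity),
                    "specificity": prop(m.specificity),
                    "ppv": prop(m.ppv),
                    "npv": prop(m.npv),
                }
                for m in self.stage_metrics
            ],
            "incidence": {k: prop(v) for k, v in self.incidence.items()},
            "recurrence": prop(self.recurrence),
            "hospital_range": (
                None if self.hospital_range is None else {
                    "min_pct": self.hospital_range[0],
                    "max_pct": self.hospital_range[1],
                    "n_hospitals": self.hospital_range[2],
                    "min_volume": self.hospital_range_min_volume,
                }),
            "counts": dict(sorted(self.counts.items())),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=False)

    def to_text(self) -> str:
        lines = ["Validation report", "=================", ""]
        lines.append("Stage metrics (% with 95% CI)")
        for m in self.stage_metrics:
            def fmt(p):
                return str(p) if p is not None else "undefined"
            tb = self.two_by_twos.get(m.stage)
            tb_txt = (f"  [tp={tb.tp} fp={tb.fp} fn={tb.fn} tn={tb.tn}]"
                      if tb else "")
            lines.append(
                f"  stage {m.stage}: sensitivity {fmt(m.sensitivity)}, "
                f"specificity {fmt(m.specificity)}, PPV {fmt(m.ppv)}, "
                f"NPV {fmt(m.npv)}{tb_txt}")
        lines.append("")
        lines.append("Incidence of dislocation by diagnosis group")
        for key, p in self.incidence.items():
            lines.append(f"  {key}: {p.k}/{p.n} = {p}")
        if self.recurrence is not None:
            lines.append("")
            lines.append(
                f"Recurrent dislocation among dislocating patients: "
                f"{self.recurrence.k}/{self.recurrence.n} = {self.recurrence}")
        if self.hospital_range is not None:
            lo, hi, nh = self.hospital_range
            lines.append("")
            lines.append(
                f"Between-hospital incidence range (volume >= "
                f"{self.hospital_range_min_volume}): {lo:.1f}% to {hi:.1f}% "
                f"across {nh} hospitals")
        if self.counts:
            lines.append("")
            lines.append("Counts")
            for key in sorted(self.counts):
                lines.append(f"  {key}: {self.counts[key]}")
        return "\n".join(lines) + "\n"


def build_report(stage_metrics: Sequence[DiagnosticMetrics],
                 two_by_twos: Mapping[int, TwoByTwo],
                 incidence: Mapping[str, ProportionEstimate],
                 recurrence: Optional[ProportionEstimate] = None,
                 hospital_range: Optional[tuple[float, float, int]] = None,
                 hospital_range_min_volume: int = 1,
                 counts: Optional[Mapping[str, int]] = None) -> ValidationReport:
    """Assemble the combined report; rendering is deterministic given inputs."""
    return ValidationReport(
        stage_metrics=list(stage_metrics),
        two_by_twos=dict(two_by_twos),
        incidence=dict(incidence),
        recurrence=recurrence,
        hospital_range=hospital_range,
        hospital_range_min_volume=hospital_range_min_volume,
        counts=dict(counts or {}),
    )
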