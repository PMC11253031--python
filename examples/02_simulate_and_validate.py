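"""Full pipeline on a synthetic registry: simulate, build the cohort,
classify at every stage, link events, and validate against the gold standard.

Generates a 20,000-THA bundle with the study-calibrated defaults, then runs
the whole analysis in memory and prints the validation report.
"""

import numpy as np

from thadisloc import (
    Source,
    build_cohort,
    build_report,
    collapse_events,
    compile_stages,
    confusion,
    default_params,
    diagnostic_metrics,
    flag_patients,
    generate_registry,
    hospital_incidence_range,
    incidence_by_group,
    recurrence_summary,
)

params = default_params(cohort_n=20_000)
bundle = generate_registry(params, seed=4)
print(f"simulated {len(bundle.thas)} THA records, "
      f"{len(bundle.contacts)} hospital contacts, "
      f"{len(bundle.gold_events)} gold dislocation events")

arthro = [t for t in bundle.thas if t.source is Source.ARTHROPLASTY_REGISTER]
fracture = [t for t in bundle.thas if t.source is Source.FRACTURE_REGISTER]
cohort = build_cohort(arthro, fracture, bundle.revisions, bundle.vitals,
                      params.inclusion_window)
print(f"cohort: {len(cohort)} (excluded: {cohort.exclusion_counts}); "
      f"mean follow-up {np.mean([w.days for _, w in cohort.members]):.0f} days")

cfg = compile_stages()
gold = {e.patient_id for e in bundle.gold_events}
tables, metrics = {}, []
for stage in range(1, 5):
    tb = confusion(cohort, gold,
                   flag_patients(cohort, bundle.contacts, cfg, stage))
    tables[stage] = tb
    metrics.append(diagnostic_metrics(tb, stage=stage))

events = collapse_events(
    [c for c in bundle.contacts if c.n_dislocations_in_admission >= 1],
    index_sides={t.patient_id: t.side for t, _ in cohort.members})
rec = recurrence_summary(events)

report = build_report(
    metrics, tables, incidence_by_group(cohort, gold),
    recurrence=rec.recurrence,
    hospital_range=hospital_incidence_range(cohort, gold, min_volume=100),
    hospital_range_min_volume=100,
    counts={"cohort": len(cohort), "gold_patients": len(gold),
            "gold_events": rec.n_events})
print()
print(report.to_text())
print("Reading: the stage-wise sensitivities recover the configured coding "
      "model (~52/70/89/95%), overall incidence sits near 2.8%, and the "
      "recurrence share sits a little under the 37% continuation because "
      "late recurrences are censored at the 1-year window end.")
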