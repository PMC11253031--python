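"""Exact binomial intervals and stage metrics from published register counts.

Feeds the per-diagnosis dislocation counts of a national THA cohort and the
patient-level 2x2 tables of the four-stage coding algorithm through the
metric layer, printing the proportions with Clopper-Pearson 95% intervals.
"""

from thadisloc import TwoByTwo, diagnostic_metrics, proportion_estimate

# (diagnosis group, cohort size, dislocating patients)
INCIDENCE_ROWS = [
    ("primary osteoarthritis", 4472, 113),
    ("acute femoral neck fracture", 269, 12),
    ("sequelae after proximal femur fracture", 226, 12),
    ("hip dysplasia", 155, 3),
    ("femoral head necrosis", 104, 4),
    ("other diagnoses", 189, 8),
]

print("1-year dislocation incidence by diagnosis, % (exact 95% CI)")
for name, n, k in INCIDENCE_ROWS:
    print(f"  {name:40s} {k:>3}/{n:<5} {proportion_estimate(k, n)}")
print(f"  {'overall':40s} 152/5415  {proportion_estimate(152, 5415)}")

# Patient-level 2x2 per algorithm stage: (tp, fp, fn, tn)
STAGE_TABLES = {
    1: TwoByTwo(79, 0, 73, 5263),
    2: TwoByTwo(106, 2, 46, 5261),
    3: TwoByTwo(135, 6, 17, 5257),
    4: TwoByTwo(144, 10, 8, 5253),
}

print("\nStaged algorithm accuracy, % (exact 95% CI)")
for stage, tb in STAGE_TABLES.items():
    m = diagnostic_metrics(tb, stage=stage)
    print(f"  stage {stage}: sensitivity {m.sensitivity}, PPV {m.ppv}")

print("\nReading: stage 1 trusts only the nominally correct code pair and "
      "finds ~52% of true dislocation patients; broadening the code sets to "
      "stage 4 lifts sensitivity to ~95% while PPV stays above 93%.")
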