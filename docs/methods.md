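# Methods

This note documents the models and procedures implemented in `thadisloc`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic data can and cannot show.

## The classifier

A hospital contact identifies a THA dislocation when a qualifying
diagnosis code and a qualifying reduction procedure code occur **on the
same contact**. The requirement of a pair (rather than either code alone)
reflects how the strictest variant of the phenotype is defined: the
nominally correct pair is `DT84.0A` (mechanical complication of a hip
prosthesis) with `KNFH2*` (reduction of a dislocated hip prosthesis;
closed, arthroscopic or open). The four cumulative stages then broaden the
admitted pairs — native-hip coding `DS73.0`/`KNFH0*` applied to a
prosthetic dislocation is a common coding slip — and finally relax the
laterality requirement.

Laterality is evaluated per code pair against the index hip:

* *must-match* stages: at least one of the two codes carries the index
  side and neither carries the contralateral side (a known-side code plus
  an unknown-side code passes);
* a known **contralateral** side on either code blocks the pair at
  must-match stages; the contact can then only qualify at stage 4. This is
  deliberate: with bilateral implants, contact-level laterality is
  genuinely ambiguous, and resolving it is exactly what stage 4 trades PPV
  for.

Stage membership is configurable through a declarative YAML spec;
compilation rejects non-cumulative specs (a later stage must cover every
earlier rule with an equal or weaker laterality requirement). The exact
composition of stages 2–3 is a reconstruction of the natural broadening
sequence (correct pair → half-correct pairs → fully native pair); the
stage spec file is the unit to swap in if an alternative code list must be
mirrored exactly. Patient-level flagging takes the minimum qualifying
stage over all contacts inside the patient's follow-up window.

## Cohort and follow-up

The analysis cohort is one primary THA per patient inside a configurable
inclusion window (default 2019-07-01 … 2019-12-31). The fracture-register
supplement is merged with the arthroplasty register on
(patient, side, date ± 1 day); the arthroplasty record wins conflicts.
For in-window bilateral patients the earlier hip is kept (same-day ties
break to the left hip — arbitrary but deterministic and logged).

Follow-up is the **closed** interval from surgery to
min(surgery + 365 d, first same-side revision, death, emigration); an
event on the day of surgery counts. Ties resolve by the precedence
revision > death > migration > horizon. The horizon is exactly 365 days;
"1 year" is not otherwise defined in day counts.

## Statistics

All proportions are k/n with exact Clopper–Pearson 95% intervals from beta
quantiles (lower bound 0 at k = 0, upper bound 100% at k = n). The method
is conservative (coverage ≥ nominal, verified by simulation in the test
suite) and is the interval that reproduces small-count register tables at
one printed decimal, where Wilson does not. Percentages are rounded
half-up to one decimal; a metric whose denominator is empty is reported as
undefined, never as 0 or 100. The 2×2 tables are patient-level, not
contact-level. One known irreconcilability in the source material: the
narrative stage-4 PPV "over 94% (85–95)" cannot be derived from the
printed stage-4 counts, which give 144/154 = 93.5% (88.4–96.8); the
package always reports the count-derived value.

## Event linking

Contacts known to carry a dislocation are merged into events by (a) shared
admission link id, (b) a start within `gap_days` (default 1) of another
qualifying contact of the same patient and compatible side at a
*different* hospital — the transfer-duplicate pattern — and (c) same-day
duplicates at one hospital. Each merged group yields
max(`n_dislocations_in_admission`) events (≥ 1) at the group's earliest
date. With contralateral events excluded upstream, the event side is the
cohort's index side; an optional `index_sides` map supplies it where code
laterality is unknown.

## The synthetic registry

The generator emulates a national half-year THA cohort with linked
hospital contacts. Defaults are calibrated to published register counts:

| parameter | default | source of calibration |
|---|---|---|
| diagnosis mix | 4472/269/226/155/104/189 of 5,415 | cohort table |
| 1-year dislocation risk per group | 113/4472 … 8/189 | dislocators per group |
| recurrence continuation *q* | 0.37, max 5 events | recurrence share |
| capture-stage distribution | (79, 27, 29, 9, 8)/152 | differenced cumulative stage capture |
| transfer-duplicate probability | 131/240 | contact partition |
| two-reduction admissions | 3/240 | 243 events in 240 contacts |
| open reductions | 2/243 | reduction types |
| false-positive contact rate | 10/5,415 /patient-year, split (0, .2, .4, .4) over stages | stage-wise false positives |
| noise contact rate | 1,370/5,415 /patient-year | reviewed non-dislocation contacts |
| death / other-revision / dislocation-revision / emigration | 2.5% / 1.8% / 0.7% / 0.2% | follow-up accounting (2.5% any-cause revision minus the 0.7% caused by dislocation; emigration ≈ 0 but kept non-zero to exercise the path) |
| hospitals | 42, lognormal volume weights (sd 1.0), multiplicative risk effect (log-sd 0.45) | hospital count and volume range |

Design choices where the generating process was open:

* **Event timing** is Weibull (shape 0.7, scale 200 d) truncated to the
  horizon — early-skewed, consistent with most dislocations of a two-year
  horizon falling in the first year. No calibration target depends on the
  timing shape. Gaps between recurrent admissions are 4 d + Exp(30 d); the
  4-day floor keeps distinct admissions from being mistaken for transfers.
* **Recurrence** is truncated-geometric: after each event a further event
  occurs with probability q = 0.37, capped at 5. This one parameter
  simultaneously gives P(≥2 events | ≥1) = 0.37 and ≈ 1.58 events per
  dislocating patient (closed form `Σ k·(1−q)q^(k−1)` truncated at 5).
* **The capture stage is drawn once per patient**, not per event: coding
  style is a property of the treating pathway, and the validation counts
  being emulated are patient-level. Independent per-event draws would
  inflate patient-level sensitivity for recurrent dislocators (stage 1
  would drift from 52% to ≈ 63%).
* **Hospital effects** are lognormal risk multipliers rescaled to a
  patient-weighted mean of exactly 1 per realisation. With only ~42
  hospitals and strong volume concentration, an unnormalised random effect
  leaves cluster-level variance in the realised marginal incidence, which
  would swamp binomial Monte-Carlo tolerances at any cohort size.
* A 10% share of patients carries a **pre-window contralateral THA**
  (exercising exclusion accounting) and 25% of acute-fracture THAs appear
  only in the fracture register (exercising the merge); both rates are
  package choices, not published values.

All sampling flows from one seeded NumPy generator in a fixed order:
cohort-level vectors first, then per-dislocator histories in patient
order, then background contacts. Identical (params, seed) give
byte-identical bundles.

### What the synthetic data does not show

Generated bundles are internally consistent by construction — the gold
annotation channel (`n_dislocations_in_admission`) reconstructs the gold
event table exactly, which is a *linker* correctness check, not evidence
about real transfer patterns. Real registers add: coding drift over time,
register-version migration artifacts, contacts spanning admissions in
messier ways, dislocations of other implants (hemiarthroplasties,
contralateral prostheses) that a reviewer would adjudicate, and
non-independent coding behaviour within hospitals. Passing calibration
tests therefore shows the pipeline recovers the *configured* structure at
scale; it does not validate the stage definitions against any real
register, which always requires a review-based gold standard.

### Observed vs configured quantities

Censoring interacts with calibration: the observed incidence in a
generated cohort sits ~1% (relative) below the configured risks because
patients censored early cannot dislocate afterwards, and the observed
recurrence share sits ≈ 1.5 points below the continuation parameter
because late recurrences fall beyond the window — both effects are also
present in the real-world quantities the defaults were calibrated to.

## Problem sizes

Calibration-recovery tests and the acceptance script use a 100,000-THA
bundle (seconds to generate and classify); unit and property tests use
300–2,000-THA bundles and brute-force oracles on cohorts of ≤ 20 patients.
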