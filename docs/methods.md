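# Methods

This note records the modelling decisions behind `ascertain`: the
validation procedure, the synthetic generative model and its closed-form
expectations, the defaults and why they were chosen, and what the tests
do and do not demonstrate.

## Validation procedure

**Unit of analysis.** Persons, not records, one cancer type at a time. A
person with several same-type registry records takes the *earliest*
in-window record as their diagnosis month (incident-case semantics). A
person with two cancer types is evaluated independently for each.

**Month precision.** Registries supply year and month of diagnosis but no
day, so every temporal comparison uses the month index
`12·year + (month − 1)`. Surrogate event days are retained solely to
break ties when choosing the first occurrence inside a month: a date with
a day sorts before one without, then by day, then by record order. This
makes first-occurrence selection deterministic without ever letting a day
influence a lag.

**Labels.** A registry case ascertained only outside ±W months is labelled
`FN_and_FP`: it is a miss for sensitivity (the case was not found near its
diagnosis) *and* a non-true-positive identification for PPV (the flagged
person does not match). Keeping one label for this group preserves both
conservation identities — `TP + FN_total = n_registry_cases` and
`TP + FP_total = n_identified` — which the property suite asserts on every
run. Specificity uses only persons without an in-window registry record of
the evaluated type; it is therefore independent of W.

**Intervals.** Wilson score intervals (via statsmodels) on all three
proportions; bounds are snapped to exactly 0/1 at k = 0 and k = n. A
symmetric normal interval is available (`ci_method="normal"`) for
comparison. The reporting convention of rounding displayed percentages
to integers is applied only in display paths; outputs retain machine
precision.

**AND-composite dating.** An AND combination ("hospital diagnosis and
surgery") reads as "diagnosed cases who also had treatment", so it is
dated by a designated *anchor* leaf — by default the first leaf, in the
shipped battery always the hospital-diagnosis leaf — rather than by the
earliest or latest component. Consequence: an AND composite's case set is
contained in every component's, but its *sensitivity* is bounded only by
the anchor's (a non-anchor component's own first date may fall outside ±W
while the anchor's does not). The property tests assert exactly this
anchor-consistent form.

**Optimal algorithm.** Selection is made explicit as a lexicographic rule:
maximise sensitivity subject to PPV ≥ a floor (default 0.80), ties broken
by higher PPV, evaluated at the largest configured window. With the
default floor this typically selects the plain hospital-diagnosis
indicator; a stricter floor can leave no qualifying algorithm, reported as
`None`.

**Exclusions.** Eligibility removes persons under the minimum baseline age
(default 45) and persons with irreconcilable linked data, operationalised
as any event dated strictly after death (month-level comparison unless
both dates carry days). The operation is idempotent and cascades to all of
the person's events and registry records.

## Synthetic cohort generator

The generator emulates the statistical structure of a state-wide linked
asset: a cohort recruited 2006–2009, a registry covering an evaluation
window (default Feb 2006 – Dec 2010, 59 months), hospital data running
from mid-2001 to mid-2014, claims from 2004, emergency data from 2005 and
death data 2006–2012. Per cancer type:

* **Incidence.** Each person becomes an incident case with probability
  `1 − (1 − p_month)^M` over the extended hospital follow-up; the
  diagnosis month is uniform over that span. Cases diagnosed after the
  registry's last month exist in hospital data but not in the registry —
  they feed the incremental-case analysis, and their rare pre-diagnosis
  admissions leak back into the window as false positives (a boundary
  artifact real studies also face).
* **Detection.** A case is coded in hospital with probability `p_code`,
  multiplied by a capture penalty for border residents (interstate
  hospitalisation loss) and for unknown spread of disease (less
  health-system contact). The event month is the diagnosis month plus a
  lag drawn from a distribution whose support includes one pre-diagnosis
  month and a tail beyond ±12 (creating `FN_and_FP` cases). Events are
  suppressed if the person has already died or the month lies outside the
  source's coverage.
* **Contamination.** Prevalent cases (diagnosed before the window, fraction
  of non-cases) are re-coded during the window with a re-coding
  probability — the mechanism behind the date-agnostic-PPV gap — and all
  persons accrue false primary-site codes at a small per-person-month
  miscode rate.
* **Mortality.** Cases die under a constant monthly case fatality from
  diagnosis; persons with no cancer follow a background monthly hazard
  from baseline. Fatal cases are certified with the primary site as an
  underlying cause with a coding probability; prevalent cases' deaths are
  cancer-certified at a lower rate; a small share of non-case deaths are
  miscertified as primary cancer, some carrying a secondary-malignancy
  (C77–C79) code elsewhere in their linked records. These three mechanisms
  make the death-record discordance triage categories recoverable from
  ground truth.
* **Treatment and other sources.** Detected cases generate surgery,
  chemotherapy and radiotherapy procedure/claim/dispensing records with
  stated probabilities (plus claim "echoes" of inpatient procedures);
  non-cases generate look-alike treatment records at background rates,
  because procedure and drug codes are not exclusive to one cancer.
  Emergency presentations are coded ICD-10 only 70% of the time (the rest
  SNOMED, unmapped), mirroring inconsistent emergency coding.

All draws come from named substreams of a single seed
(`default_rng([seed, crc32(stream)])`), so identical configurations are
byte-identical and adding a source never perturbs another's stream. Every
emitted record is tagged in `GroundTruth.event_mechanisms` with exactly
one generating mechanism.

**Default parameter values** were chosen once as a realistic operating
point for a 45+ cohort of this size, not calibrated to reproduce any
published table (the generator's purpose is parameter recovery, and
calibrating to published estimates would be circular): colorectal monthly
incidence 1.45×10⁻⁴ and lung 6.6×10⁻⁵ (≈430 and ≈195 in-window cases per
50,000 persons); `p_code` 0.97 (colorectal) and 0.88 (lung); colorectal
lag mass 0.87 at zero months, lung only 0.55 with a longer tail; border
fraction 8% with capture penalty 0.5; prevalent fractions 0.3% and 0.12%;
miscode rates 5×10⁻⁶ and 3×10⁻⁶ per person-month; case fatality 0.012 and
0.040 per month; background mortality 0.001 per month. Note that the lag
distribution describes the *latent* coding delay; observed identification
is additionally truncated by death, so a fast-fatal cancer's realised
sensitivity sits well below `p_code · P(|lag| ≤ W)`.

## Closed-form expectations

`expected_metrics` computes the expected sensitivity, specificity and PPV
of the hospital primary-diagnosis indicator *exactly* under the generative
model, by total probability rather than simulation: for each stratum
(border × unknown-spread), each diagnosis month and each death month, it
forms the distribution of the first qualifying event month — the true
coded admission, a prevalent re-code, or the first miscode — through its
survival function, and classifies it against ±W. Non-case ascertainment
marginalises over the background death-month distribution (recruitment
month convolved with the geometric hazard). A test verifies the
computation against an independent exhaustive enumeration of the whole
outcome space on a two-month window to 10⁻⁹.

The one knowing approximation: a person carrying *both* cancer types has
one type's death clock truncating the other's coding, a set of measure
`O(q₁·q₂)` (≈0.6 persons per 50,000 at the defaults) that the per-cancer
expectation ignores. PPV is a ratio of expectations, appropriate at the
cohort sizes used.

Parameter recovery is asserted over 30 seeds at n = 50,000: the 95% Wilson
interval around each seed's estimate must cover the expected value with
empirical coverage ≥ 90% (sensitivity per cancer type, and pooled over all
three metrics × two cancers). Exact binomial computation shows the Wilson
interval's nominal coverage at these operating points is ≈95.1%, so the
threshold leaves honest slack for interval discreteness without admitting
generator bias.

## What the synthetic tests do not show

The generator reproduces the *mechanisms* of imperfect ascertainment, not
the messiness of real extracts: no linkage error (person identity is taken
as resolved), no coding-practice drift over calendar time, no correlation
between comorbidity and coding quality beyond the spread/border penalties,
single-episode detection rather than repeated admissions per case, and
drug/procedure code lists reduced to small synthetic sets. Passing the
suite demonstrates that the engines are correct and the estimators
unbiased under a known truth — not that any particular real-world
indicator will achieve the synthetic operating characteristics.

## Numerical conventions and scale choices

Evaluation windows are validated against per-source coverage before any
computation; a window outside coverage is a configuration error, not an
empty result. Degenerate inputs are reported as absent rather than forced:
PPV with nothing identified, percentage increase with a zero base and
date-agnostic PPV of an empty ascertainment set are all `None`, and empty
mismatch strata are flagged rather than normalised. Rounding of reported
percentages to table precision happens only at display time.

Test problem sizes (2,000–50,000 persons; 30 recovery seeds; 110
randomised oracle fixtures of ≤ 200 persons) were chosen so the full suite
exercises every engine at cohort scale while completing in a few minutes
on one CPU; the acceptance script's demonstration run uses 50,000 persons,
the size at which binomial noise on sensitivity is ±3% and on specificity
±0.03%.
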