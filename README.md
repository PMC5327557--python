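# ascertain

Validation of cancer **case-ascertainment algorithms** in linked
administrative health data.

Population cancer registries are the gold standard for identifying incident
cancer cases, but their data are released years in arrears. Cohort studies
linked to routinely collected data — hospital admissions, emergency
presentations, medical and pharmaceutical claims, death records — can
instead flag cases from *surrogate indicators*: code-list rules such as
"an inpatient diagnosis of C18–C20" or "a death record with C34 as a cause".
`ascertain` is a toolkit for building those indicators, validating them
against a registry, and quantifying what is gained (earlier, more numerous
cases) and lost (missed and spurious cases) by relying on them. It is aimed
at epidemiologists and data-linkage analysts working with person-level
linked extracts.

Because real linked extracts are privacy-restricted, the package ships a
**synthetic linked-cohort generator** with full ground truth: per-cancer
incidence over a study window, month-lagged probabilistic hospital coding,
interstate-capture loss for border residents, prevalent-case re-coding,
random miscoding, and death certification with cause-of-death noise. Every
pipeline stage runs, and is tested, with no external data.

## The model

For one cancer type, one indicator and a matching window of ±W months,
each person in the evaluated cohort receives exactly one label. Writing
`d` for the month of the earliest in-window registry diagnosis and `a`
for the indicator's first-occurrence month:

* **TP** — registry case with `|a − d| ≤ W`;
* **FN** — registry case never ascertained in the window;
* **FN∧FP** — registry case ascertained only outside ±W (counts against
  *both* the sensitivity and the PPV denominator);
* **FP** — ascertained person with no in-window registry record;
* **TN** — everyone else.

All dates are compared at month precision (registries release no day of
diagnosis); event days are used only to pick the first occurrence within a
month. From the label counts,

```
sensitivity = TP / n_registry_cases
specificity = TN / (n_evaluated − n_registry_cases)
PPV         = TP / n_identified
```

with 95% Wilson score intervals on each proportion. Around this core the
package provides the OR/AND combination algebra over indicators (AND
composites dated by a designated *anchor* leaf), cumulative lag profiles,
stratified characterisation of missed cases, triage of death-record
discordances, date-agnostic PPV, and incremental-case counting past the
registry's final month.

## A worked example

`examples/02_validate_hospital_indicator.py` generates a 20,000-person
synthetic cohort and validates the hospital colorectal-diagnosis indicator
(ICD-10 C18–C20, ±12 months):

```
registry cases in window : 166
persons identified       : 175
true positives           : 153
sensitivity   92.2%  (95% CI 87.1-95.4)
PPV           87.4%  (95% CI 81.7-91.5)
specificity  99.90% (95% CI 99.84-99.93)
```

Here the hospital data found 92% of the registry's incident colorectal
cancers; 87% of the persons it flagged were window-matched registry cases;
and fewer than 0.1% of non-cases were flagged. The other examples cover
simulation (`01`), combination algorithms and optimal-algorithm selection
(`03`), lag profiles and missed-case strata (`04`), extending follow-up
past the registry and date-agnostic PPV (`05`), and parameter recovery
against the generator's closed-form expectations (`06`).

A thin CLI wraps the same pipeline:

```bash
ascertain all --n-persons 50000 --seed 1 --outdir results/demo
ascertain simulate --n-persons 20000 --seed 7 --outdir scratch/cohort
ascertain validate --input-dir scratch/cohort --outdir results/from_disk
```

Reports are plain CSV/JSON (`metrics.csv`, `lag_profiles.csv`,
`optimal.json`, `mismatch.json`, `triage.json`, `increments.json`) plus a
manifest with the seed and a configuration hash; reruns with the same seed
are byte-identical.

## Layout

```
src/ascertain/
  dates.py        month-precision StudyDate and month-index arithmetic
  cohort.py       Cohort container, validation, eligibility exclusions
  io.py           schema-driven CSV readers/writers (wide or long code slots)
  indicators.py   code-list indicators, first occurrence, OR/AND algebra
  validation.py   classification, metrics + CIs, lag/mismatch/triage/increments
  synthetic.py    synthetic linked-cohort generator with ground truth
  expected.py     exact expected metrics under the generative model
  config.py       default indicator battery, YAML run configuration
  pipeline.py     end-to-end runs and report bundles
  cli.py          simulate / extract / validate / report / all
```

See `docs/methods.md` for the generative model, its assumptions and
limitations, and the numerical conventions used throughout.
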