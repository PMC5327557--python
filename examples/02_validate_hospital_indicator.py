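"""Validate the hospital cancer-diagnosis indicator against the registry.

A person counts as ascertained when any inpatient admission in the
evaluation window carries a primary-site diagnosis code (C18-C20 for
colorectal cancer); the ascertainment date is the first such admission.
A true positive requires that date to fall within +/-12 months of the
registry's (month-precision) diagnosis date.
"""

from ascertain import (
    classify_cases, compute_metrics, default_config, extract_indicator,
    generate_cohort,
)
from ascertain.config import default_indicators

cfg = default_config(n_persons=20_000, seed=1)
cohort, _ = generate_cohort(cfg)
defs, _ = default_indicators(cfg.cancers[0])

asc = extract_indicator(
    cohort.events, defs["colorectal_apdc_dx"], cfg.eval_window, cohort.coverage
)
mc = classify_cases(asc, cohort.registry, "colorectal", cfg.eval_window, 12)
m = compute_metrics(mc, cohort.n_persons)

print(f"registry cases in window : {m.n_registry_cases}")
print(f"persons identified       : {m.n_identified}")
print(f"true positives           : {m.tp}")
lo, hi = m.sensitivity_ci
print(f"sensitivity  {100*m.sensitivity:5.1f}%  (95% CI {100*lo:.1f}-{100*hi:.1f})")
lo, hi = m.ppv_ci
print(f"PPV          {100*m.ppv:5.1f}%  (95% CI {100*lo:.1f}-{100*hi:.1f})")
lo, hi = m.specificity_ci
print(f"specificity  {100*m.specificity:5.2f}% (95% CI {100*lo:.2f}-{100*hi:.2f})")
print("\nSensitivity is the share of registry cases the hospital data found;")
print("PPV the share of hospital-flagged persons who are window-matched")
print("registry cases; specificity the share of non-cases left unflagged.")
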