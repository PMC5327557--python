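"""Analytic expectations for the synthetic cohort's hospital-diagnosis indicator.

For the primary surrogate — an inpatient diagnosis code for the cancer's
primary site — every probability in the generative model is known, so the
expected sensitivity, specificity and PPV can be computed exactly by total
probability rather than estimated by simulation.  The calculation
enumerates, for each stratum (border residence × unknown spread), each
true diagnosis month and each death month, the distribution of the *first*
qualifying event month (the true coded admission, a prevalent re-coding,
or the first random miscode) and classifies it against the ±W matching
window, exactly mirroring the validation engine's person-level rules:

* TP: first qualifying date within ±W of the registry month;
* FN + FP (both denominators): a registry case ascertained only outside ±W;
* FP: any qualifying date for a person with no in-window registry record —
  including true cases diagnosed *after* the registry's last month whose
  pre-diagnosis admission leaks back into the window.

These expectations serve as the oracle for parameter-recovery tests: the
empirical estimates from a generated cohort must sit inside their Wilson
intervals around these values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import CancerModel, SyntheticCohortConfig

__all__ = ["ExpectedMetrics", "expected_metrics"]


@dataclass(frozen=True)
class ExpectedMetrics:
    """Expected validity of the inpatient primary-diagnosis indicator."""

    cancer_type: str
    window_months: int
    sensitivity: float
    specificity: float
    ppv: float
    e_registry_cases: float   # expected count in a cohort of cfg.n_persons
    e_identified: float
    e_tp: float


def _strata(cfg: SyntheticCohortConfig, cm: CancerModel):
    """(weight, detection probability) over border × unknown-spread strata."""
    bf = cfg.demographics.border_fraction
    pu = dict(cm.spread_dist).get("unknown", 0.0)
    out = []
    for is_border, wb in ((True, bf), (False, 1 - bf)):
        for is_unknown, wu in ((True, pu), (False, 1 - pu)):
            p = cm.p_code
            if is_border:
                p *= cfg.border_capture_penalty
            if is_unknown:
                p *= cm.unknown_spread_penalty
            out.append((wb * wu, p))
    return out


def _death_month_pmf(cfg: SyntheticCohortConfig, m1: int) -> tuple[np.ndarray, int, float]:
    """Marginal death-month pmf for persons on the background-mortality clock.

    Returns ``(pmf, first_month, p_survives_past_m1)`` with ``pmf[j]`` the
    probability of dying in month ``first_month + j`` (months up to the end
    of the evaluation window).
    """
    b = cfg.background_mortality_monthly
    b0, b1 = cfg.recruitment_start.month_index, cfg.recruitment_end.month_index
    if b <= 0:
        return np.zeros(0), b0, 1.0
    months = np.arange(b0, m1 + 1)
    pmf = np.zeros(len(months))
    nb = b1 - b0 + 1
    for B in range(b0, b1 + 1):
        t = months - B
        ok = t >= 0
        pmf[ok] += (1.0 / nb) * b * (1 - b) ** t[ok]
    return pmf, b0, float(1.0 - pmf.sum())


def _case_label_probs(
    cm: CancerModel, p_det: float, d: int, m0: int, m1: int, W: int
) -> tuple[float, float]:
    """(P(TP), P(any in-window ascertainment)) for a case diagnosed in month d."""
    offsets, pvals = cm.lag.offsets, cm.lag.pvals
    r = cm.miscode_monthly
    f = cm.case_fatality_monthly
    Lmax = int(offsets.max())
    t_cap = (m1 - d) + max(Lmax, W) + 1  # beyond this, death changes nothing

    def survival(m: int, pE: dict, p_noE: float, last_alive: int) -> float:
        # P(first qualifying month >= m)
        tail = p_noE + sum(p for e, p in pE.items() if e >= m)
        n_before = max(0, min(last_alive, m1, m - 1) - m0 + 1)
        return tail * (1 - r) ** n_before

    def probs_given_t(t: int) -> tuple[float, float]:
        pE = {}
        for L, pL in zip(offsets, pvals):
            e = d + int(L)
            if L <= t and m0 <= e <= m1:
                pE[e] = pE.get(e, 0.0) + p_det * pL
        p_noE = 1.0 - sum(pE.values())
        last_alive = d + t
        s_end = survival(m1 + 1, pE, p_noE, last_alive)
        p_any = 1.0 - s_end
        a, bb = max(d - W, m0), min(d + W, m1)
        if a > bb:
            return 0.0, p_any
        p_tp = survival(a, pE, p_noE, last_alive) - survival(bb + 1, pE, p_noE, last_alive)
        return p_tp, p_any

    if f <= 0:
        return probs_given_t(t_cap)
    e_tp = e_any = 0.0
    p_tail = 1.0
    for t in range(t_cap):
        pt = f * (1 - f) ** t
        p_tail -= pt
        tp, any_ = probs_given_t(t)
        e_tp += pt * tp
        e_any += pt * any_
    tp, any_ = probs_given_t(t_cap)
    e_tp += p_tail * tp
    e_any += p_tail * any_
    return e_tp, e_any


def expected_metrics(
    cfg: SyntheticCohortConfig, window_months: int = 12, cancer_type: str | None = None
) -> ExpectedMetrics | dict[str, ExpectedMetrics]:
    """Exact expected sensitivity/specificity/PPV under the generative model.

    With ``cancer_type=None`` a dict keyed by cancer name is returned.
    The only approximation concerns persons carrying two cancer types at
    once (one type's death clock truncating the other's coding), a set of
    measure ``O(q1*q2)`` of the cohort.
    """
    cfg.validate()
    if cancer_type is None:
        return {
            cm.name: expected_metrics(cfg, window_months, cm.name) for cm in cfg.cancers
        }
    cm = next((c for c in cfg.cancers if c.name == cancer_type), None)
    if cm is None:
        raise KeyError(f"no cancer type {cancer_type!r} in config")

    W = window_months
    m0, m1 = cfg.study_start.month_index, cfg.study_end.month_index
    cov1 = cfg.followup_end.month_index
    M = m1 - m0 + 1
    M_ext = cov1 - m0 + 1
    q = 1.0 - (1.0 - cm.monthly_incidence) ** M_ext
    r = cm.miscode_monthly
    strata = _strata(cfg, cm)

    # --- in-window cases -------------------------------------------------
    e_tp = e_any_case = 0.0
    for d in range(m0, m1 + 1):
        for w, p_det in strata:
            tp, any_ = _case_label_probs(cm, p_det, d, m0, m1, W)
            e_tp += (q / M_ext) * w * tp
            e_any_case += (q / M_ext) * w * any_

    # --- cases diagnosed after the registry's last month ------------------
    e_fp_post = 0.0
    offsets, pvals = cm.lag.offsets, cm.lag.pvals
    for d in range(m1 + 1, cov1 + 1):
        for w, p_det in strata:
            p_event = p_det * float(pvals[(d + offsets >= m0) & (d + offsets <= m1)].sum())
            p_any = 1.0 - (1.0 - p_event) * (1 - r) ** M
            e_fp_post += (q / M_ext) * w * p_any

    # --- persons with no incident diagnosis ------------------------------
    pmf, first, p_alive = _death_month_pmf(cfg, m1)
    alive_terms = []  # (probability, alive months in evaluation window)
    for j, p in enumerate(pmf):
        if p > 0:
            alive_terms.append((float(p), max(0, min(first + j, m1) - m0 + 1)))
    alive_terms.append((p_alive, M))

    p_nc = 1.0 - sum(p * (1 - r) ** a for p, a in alive_terms)
    p_prev = 1.0 - sum(
        p * (1 - r) ** a * (1.0 - cm.recode_probability * a / M) for p, a in alive_terms
    )
    pp = cm.prevalent_fraction
    e_fp_noncase = (1.0 - q) * ((1.0 - pp) * p_nc + pp * p_prev)

    # --- assemble ---------------------------------------------------------
    w_case_in = q * M / M_ext
    e_fp = e_fp_post + e_fp_noncase
    n_noncase = (1.0 - q) + q * (M_ext - M) / M_ext
    sensitivity = e_tp / w_case_in
    specificity = 1.0 - e_fp / n_noncase
    e_identified = e_any_case + e_fp
    ppv = e_tp / e_identified if e_identified > 0 else float("nan")
    return ExpectedMetrics(
        cancer_type=cm.name,
        window_months=W,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        e_registry_cases=cfg.n_persons * w_case_in,
        e_identified=cfg.n_persons * e_identified,
        e_tp=cfg.n_persons * e_tp,
    )
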