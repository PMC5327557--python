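"""Generator determinism, ground-truth consistency and closed-form oracles."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from ascertain import (
    classify_cases,
    compute_metrics,
    default_config,
    expected_metrics,
    extract_indicator,
    generate_cohort,
    stratify_mismatches,
    triage_death_fps,
    wilson_ci,
    write_cohort,
)
from ascertain.config import default_indicators
from ascertain.errors import ConfigurationError
from ascertain.synthetic import (
    CancerModel,
    Demographics,
    LagDistribution,
    SyntheticCohortConfig,
)

from .conftest import noiseless_config, sd


def _apdc_dx(cfg, cancer="colorectal"):
    cm = next(c for c in cfg.cancers if c.name == cancer)
    defs, _ = default_indicators(cm)
    return defs[f"{cancer}_apdc_dx"]


def _validate_apdc(cfg, cancer="colorectal", W=12, seed=None):
    cohort, truth = generate_cohort(cfg, seed=seed)
    asc = extract_indicator(cohort.events, _apdc_dx(cfg, cancer),
                            cfg.eval_window, cohort.coverage)
    mc = classify_cases(asc, cohort.registry, cancer, cfg.eval_window, W)
    return cohort, truth, compute_metrics(mc, cohort.n_persons), mc


class TestGenerator:
    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        cfg = default_config(n_persons=1500, seed=42)
        for run in ("a", "b"):
            cohort, _ = generate_cohort(cfg)
            write_cohort(cohort, tmp_path / run)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seeds_differ(self):
        a, _ = generate_cohort(default_config(n_persons=800, seed=1))
        b, _ = generate_cohort(default_config(n_persons=800, seed=2))
        assert not a.persons.equals(b.persons)

    def test_registry_contains_exactly_the_true_incident_and_prevalent_cases(self):
        cfg = default_config(n_persons=6000, seed=3)
        cohort, truth = generate_cohort(cfg)
        m1 = cfg.study_end.month_index
        for cm in cfg.cancers:
            t = truth.persons
            want_incident = set(
                t.loc[t[f"case_{cm.name}"] & (t[f"dx_month_{cm.name}"] <= m1), "person_id"]
            )
            want_prev = set(t.loc[t[f"prevalent_{cm.name}"], "person_id"])
            reg = cohort.registry[cohort.registry["cancer_type"] == cm.name]
            from ascertain.cohort import month_idx_of
            in_win = month_idx_of(reg["diagnosis_date"]) >= cfg.study_start.month_index
            assert set(reg.loc[in_win, "person_id"]) == want_incident
            assert set(reg.loc[~in_win, "person_id"]) == want_prev

    def test_every_event_has_exactly_one_generating_mechanism(self):
        cohort, truth = generate_cohort(default_config(n_persons=4000, seed=9))
        rids = set(cohort.events["record_id"])
        mech = truth.event_mechanisms
        assert set(mech["record_id"]) == rids
        assert not mech["record_id"].duplicated().any()

    def test_invalid_probability_rejected(self):
        cfg = default_config(n_persons=10)
        bad = dataclasses.replace(cfg, border_capture_penalty=1.5)
        with pytest.raises(ConfigurationError):
            bad.validate()
        with pytest.raises(ConfigurationError):
            LagDistribution.from_dict({0: 0.6, 1: 0.6})


class TestLimitingBehaviour:
    def test_noiseless_cohort_scores_perfectly(self):
        cfg = noiseless_config(n_persons=3000, seed=5)
        for cancer in ("colorectal", "lung"):
            _, _, m, _ = _validate_apdc(cfg, cancer)
            assert m.sensitivity == 1.0
            assert m.specificity == 1.0
            assert m.ppv == 1.0
        em = expected_metrics(cfg, 12, "colorectal")
        # analytic values accumulate float error; the estimates above are exact
        assert em.sensitivity == pytest.approx(1.0, abs=1e-12)
        assert em.specificity == pytest.approx(1.0, abs=1e-12)
        assert em.ppv == pytest.approx(1.0, abs=1e-12)

    def test_zero_coding_probability_finds_nothing(self):
        cfg = noiseless_config(n_persons=1500, seed=6)
        cancers = tuple(dataclasses.replace(c, p_code=0.0) for c in cfg.cancers)
        cfg = dataclasses.replace(cfg, cancers=cancers)
        _, _, m, _ = _validate_apdc(cfg)
        assert m.sensitivity == 0.0 and m.specificity == 1.0 and m.ppv is None
        em = expected_metrics(cfg, 12, "colorectal")
        assert em.sensitivity == 0.0 and em.specificity == 1.0

    def test_detection_probability_passes_straight_through(self):
        cfg = noiseless_config(n_persons=10, seed=0)
        cancers = tuple(dataclasses.replace(c, p_code=0.8) for c in cfg.cancers)
        # no lag tail, no truncation: expected sensitivity is exactly p_code
        cfg = dataclasses.replace(cfg, cancers=cancers)
        em = expected_metrics(cfg, 12, "colorectal")
        assert em.sensitivity == pytest.approx(0.8, abs=1e-12)


def _tiny_config() -> SyntheticCohortConfig:
    cm = CancerModel(
        name="colorectal",
        codes=("C18", "C19", "C20"),
        history_code="Z85.0",
        emission_codes=("C18.9",),
        secondary_code="C78.5",
        monthly_incidence=0.1,
        p_code=0.7,
        lag=LagDistribution.from_dict({-1: 0.2, 0: 0.5, 1: 0.2, 2: 0.1}),
        unknown_spread_penalty=0.5,
        spread_dist=(("localised", 0.7), ("unknown", 0.3)),
        prevalent_fraction=0.2,
        recode_probability=0.6,
        miscode_monthly=0.05,
        case_fatality_monthly=0.3,
        p_emergency=0.0,
        history_probability=0.0,
        prevalent_history_probability=0.0,
        noncase_death_cause_fp=0.0,
    )
    return SyntheticCohortConfig(
        n_persons=3,
        seed=0,
        study_start=sd(2006, 2),
        study_end=sd(2006, 3),
        followup_end=sd(2006, 4),
        recruitment_start=sd(2006, 1),
        recruitment_end=sd(2006, 1),
        registry_history_start=sd(2005, 11),
        border_capture_penalty=0.5,
        background_mortality_monthly=0.1,
        demographics=Demographics(border_fraction=0.25),
        cancers=(cm,),
    )


def _enumerate_tiny(cfg: SyntheticCohortConfig, W: int):
    """Exhaustive total-probability enumeration of the tiny generative model.

    Walks the whole outcome space person by person — case status, diagnosis
    month, death offset, detection and lag, every miscode pattern over the
    evaluation months, prevalence and re-coding — sharing no code with
    ``expected_metrics``.
    """
    cm = cfg.cancers[0]
    m0, m1 = cfg.study_start.month_index, cfg.study_end.month_index
    cov1 = cfg.followup_end.month_index
    M = m1 - m0 + 1
    M_ext = cov1 - m0 + 1
    q = 1 - (1 - cm.monthly_incidence) ** M_ext
    r = cm.miscode_monthly
    f = cm.case_fatality_monthly
    b = cfg.background_mortality_monthly
    b0 = cfg.recruitment_start.month_index
    bf = cfg.demographics.border_fraction
    pu = dict(cm.spread_dist)["unknown"]

    T_MAX = 12

    def t_probs(hazard):
        out = [(t, hazard * (1 - hazard) ** t) for t in range(T_MAX)]
        out.append((10_000, (1 - hazard) ** T_MAX))
        return out

    p_tp = p_fnfp = p_fn = p_case_in = p_fp = p_noncase = 0.0

    strata = []
    for is_b, wb in ((True, bf), (False, 1 - bf)):
        for is_u, wu in ((True, pu), (False, 1 - pu)):
            pdet = cm.p_code * (cfg.border_capture_penalty if is_b else 1) \
                * (cm.unknown_spread_penalty if is_u else 1)
            strata.append((wb * wu, pdet))

    eval_months = list(range(m0, m1 + 1))

    def miscode_patterns(allowed):
        for bits in itertools.product([0, 1], repeat=len(allowed)):
            p = 1.0
            months = []
            for m, bit in zip(allowed, bits):
                p *= r if bit else 1 - r
                if bit:
                    months.append(m)
            yield p, months

    # --- cases -----------------------------------------------------------
    for d in range(m0, cov1 + 1):
        p_d = q / M_ext
        in_window = d <= m1
        if in_window:
            p_case_in += p_d
        for w, pdet in strata:
            for t, p_t in t_probs(f):
                death = d + t
                det_branches = [(1 - pdet, None)]
                for L, pL in zip(cm.lag.offsets, cm.lag.pvals):
                    e = d + int(L)
                    ok = L <= t and e <= cov1 and e <= death
                    det_branches.append((pdet * pL, e if ok else None))
                allowed = [m for m in eval_months if m <= death]
                for p_det_branch, e in det_branches:
                    e_eval = e if (e is not None and m0 <= e <= m1) else None
                    for p_mis, months in miscode_patterns(allowed):
                        p = p_d * w * p_t * p_det_branch * p_mis
                        firsts = ([e_eval] if e_eval is not None else []) + months
                        first = min(firsts) if firsts else None
                        if in_window:
                            if first is None:
                                p_fn += p
                            elif abs(first - d) <= W:
                                p_tp += p
                            else:
                                p_fnfp += p
                        else:
                            if first is not None:
                                p_fp += p

    # --- persons without an incident diagnosis ---------------------------
    pp = cm.prevalent_fraction
    for prev, p_prev in ((True, (1 - q) * pp), (False, (1 - q) * (1 - pp))):
        for t, p_t in t_probs(b):
            death = b0 + t
            allowed = [m for m in eval_months if m <= death]
            recode_branches = [(1.0, False)]
            if prev:
                # re-code drawn with prob p, month uniform over the window,
                # emitted only while the person is alive
                recode_branches = [
                    (cm.recode_probability / M, u <= death) for u in eval_months
                ] + [(1 - cm.recode_probability, False)]
            for p_rc, recoded in recode_branches:
                for p_mis, months in miscode_patterns(allowed):
                    p = p_prev * p_t * p_rc * p_mis
                    if months or recoded:
                        p_fp += p

    p_noncase = 1.0 - p_case_in
    sens = p_tp / p_case_in
    spec = 1.0 - p_fp / p_noncase
    ppv = p_tp / (p_tp + p_fnfp + p_fp)
    return sens, spec, ppv


class TestClosedFormOracle:
    @pytest.mark.parametrize("W", [0, 1])
    def test_expected_metrics_match_exhaustive_enumeration(self, W):
        cfg = _tiny_config()
        sens, spec, ppv = _enumerate_tiny(cfg, W)
        em = expected_metrics(cfg, W, "colorectal")
        assert em.sensitivity == pytest.approx(sens, abs=1e-9)
        assert em.specificity == pytest.approx(spec, abs=1e-9)
        assert em.ppv == pytest.approx(ppv, abs=1e-9)

    def test_single_seed_recovery_within_99pct_interval(self):
        cm = CancerModel(
            name="colorectal",
            codes=("C18", "C19", "C20"),
            history_code="Z85.0",
            emission_codes=("C18.9",),
            secondary_code="C78.5",
            monthly_incidence=1.45e-4,
            p_code=0.95,
            lag=LagDistribution.from_dict({-1: 0.03, 0: 0.85, 1: 0.10, 13: 0.02}),
            miscode_monthly=5e-6,
            case_fatality_monthly=0.01,
            p_emergency=0.0,
        )
        cfg = SyntheticCohortConfig(n_persons=50_000, seed=20, cancers=(cm,))
        _, _, m, _ = _validate_apdc(cfg)
        em = expected_metrics(cfg, 12, "colorectal")
        lo, hi = wilson_ci(m.tp, m.n_registry_cases, level=0.99)
        assert lo <= em.sensitivity <= hi


class TestStructuralEffects:
    def test_more_miscoding_means_lower_specificity_and_ppv(self):
        rates = (0.0, 2e-5, 2e-4)
        expected_specs, observed_specs, observed_ppvs = [], [], []
        for r in rates:
            base = default_config(n_persons=20_000, seed=31)
            cancers = tuple(
                dataclasses.replace(c, miscode_monthly=r) for c in base.cancers
            )
            cfg = dataclasses.replace(base, cancers=cancers)
            expected_specs.append(expected_metrics(cfg, 12, "colorectal").specificity)
            _, _, m, _ = _validate_apdc(cfg)
            observed_specs.append(m.specificity)
            observed_ppvs.append(m.ppv)
        assert expected_specs[0] > expected_specs[1] > expected_specs[2]
        assert observed_specs[0] > observed_specs[1] > observed_specs[2]
        assert observed_ppvs[0] > observed_ppvs[2]

    def test_border_capture_penalty_shows_up_in_mismatch_strata(self):
        base = default_config(n_persons=30_000, seed=8)
        cfg = dataclasses.replace(
            base,
            border_capture_penalty=0.3,
            demographics=Demographics(border_fraction=0.2),
        )
        cohort, _, m, mc = _validate_apdc(cfg)
        rep = stratify_mismatches(mc, cohort.persons, cohort.registry)
        assert rep.groups["non_matches"].border_share > rep.groups["matches"].border_share

    def test_death_record_discordance_is_recoverable(self):
        base = default_config(n_persons=40_000, seed=12)
        cancers = tuple(
            dataclasses.replace(
                c, prevalent_fraction=0.004, noncase_death_cause_fp=0.02,
                prevalent_death_cause_coding=0.8,
            )
            for c in base.cancers
        )
        cfg = dataclasses.replace(base, cancers=cancers)
        cohort, truth, *_ = _validate_apdc(cfg)
        cm = cfg.cancers[1]  # lung, mirroring the fatal-cancer use case
        defs, _ = default_indicators(cm)
        asc = extract_indicator(cohort.events, defs["lung_codurf_cause"],
                                cfg.eval_window, cohort.coverage)
        mc = classify_cases(asc, cohort.registry, "lung", cfg.eval_window, 12)
        tri = triage_death_fps(mc, cohort.events, cohort.registry, "lung")
        fp_ids = set(mc.labels.loc[mc.labels["label"] == "FP", "person_id"])
        assert tri.total == len(fp_ids)
        assert tri.counts["registry_prior_to_window"] > 0
        assert tri.counts["possible_secondary"] > 0
        assert tri.counts["other_disease"] > 0
        # every prevalent-cause death among the FPs is triaged as prior-period
        t = truth.persons.set_index("person_id")
        assigned = tri.assignments.set_index("person_id")["category"]
        for pid in fp_ids:
            if t.loc[pid, "prevalent_lung"]:
                assert assigned[pid] == "registry_prior_to_window"
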