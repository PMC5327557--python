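"""Temporal matching, diagnostic accuracy, lag profiles and follow-up analyses."""

import numpy as np
import pandas as pd
import pytest

from ascertain import (
    AscertainmentSet,
    Person,
    StudyDate,
    classify_cases,
    compute_metrics,
    count_incremental_cases,
    date_agnostic_ppv,
    lag_profile,
    persons_frame,
    stratify_mismatches,
    triage_death_fps,
    wilson_ci,
)
from ascertain.validation import MatchClassification

from .conftest import WINDOW, brute_classify, random_events, random_registry, sd


def _registry(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "cancer_type", "diagnosis_date",
                       "spread_of_disease", "age_at_diagnosis"]
    )


def _mc(labels, cancer="colorectal", W=12):
    df = pd.DataFrame(
        [(pid, lab, lag, pd.NA, pd.NA) for pid, lab, lag in labels],
        columns=["person_id", "label", "lag_months", "dx_month_idx", "asc_month_idx"],
    )
    df["lag_months"] = df["lag_months"].astype("Int64")
    return MatchClassification(cancer, "test", W, WINDOW, df)


class TestClassification:
    REG = _registry([("P1", "colorectal", "2008-03", "localised", 70.0)])

    def test_within_window_is_true_positive(self):
        asc = AscertainmentSet("x", {"P1": sd(2008, 5, 2)})
        mc = classify_cases(asc, self.REG, "colorectal", WINDOW, 12)
        assert mc.labels.set_index("person_id")["label"].to_dict() == {"P1": "TP"}
        assert mc.labels["lag_months"].iloc[0] == 2

    def test_thirteen_month_lag_counts_against_both_denominators(self):
        asc = AscertainmentSet("x", {"P1": sd(2009, 4)})
        mc = classify_cases(asc, self.REG, "colorectal", WINDOW, 12)
        assert mc.labels["label"].iloc[0] == "FN_and_FP"
        assert mc.n_registry_cases == 1 and mc.n_identified == 1
        m = compute_metrics(mc, 100)
        assert m.sensitivity == 0.0 and m.ppv == 0.0

    def test_empty_ascertainment_gives_all_fn(self):
        mc = classify_cases(AscertainmentSet("x", {}), self.REG, "colorectal", WINDOW, 12)
        assert mc.labels["label"].tolist() == ["FN"]
        m = compute_metrics(mc, 100)
        assert m.specificity == 1.0 and m.ppv is None

    def test_earliest_in_window_registry_record_defines_diagnosis(self):
        reg = _registry([
            ("P1", "colorectal", "2004-01", "localised", 66.0),   # pre-window: ignored
            ("P1", "colorectal", "2009-05", "localised", 71.0),
            ("P1", "colorectal", "2008-03", "localised", 70.0),
        ])
        asc = AscertainmentSet("x", {"P1": sd(2008, 3, 4)})
        mc = classify_cases(asc, reg, "colorectal", WINDOW, 12)
        assert mc.labels["lag_months"].iloc[0] == 0

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(5, 200))
            events = random_events(rng, n)
            registry = random_registry(rng, n)
            from ascertain import extract_indicator
            from .conftest import CRC_DX_FOR_TESTS
            asc = extract_indicator(events, CRC_DX_FOR_TESTS, WINDOW)
            for W in (3, 12):
                mc = classify_cases(asc, registry, "colorectal", WINDOW, W)
                got = mc.labels.set_index("person_id")["label"].to_dict()
                assert got == brute_classify(asc.cases, registry, "colorectal", WINDOW, W)


class TestMetrics:
    def test_reconstruction_from_published_style_marginals(self):
        # 2253 registry cases, 2338 identified, TP = round(0.95 * 2253) = 2140
        labels = [("R%d" % i, "TP", 0) for i in range(2140)]
        labels += [("F%d" % i, "FN", None) for i in range(113)]
        labels += [("X%d" % i, "FP", None) for i in range(198)]
        m = compute_metrics(_mc(labels), n_evaluated=266_794)
        assert m.n_registry_cases == 2253 and m.n_identified == 2338
        assert round(100 * m.sensitivity, 1) == 95.0
        assert round(100 * m.specificity, 1) == 99.9
        half = (m.sensitivity_ci[1] - m.sensitivity_ci[0]) / 2
        assert half <= 0.012

    def test_perfect_indicator_scores_one_everywhere(self):
        m = compute_metrics(_mc([("a", "TP", 0), ("b", "TP", 1)]), 50)
        assert (m.sensitivity, m.specificity, m.ppv) == (1.0, 1.0, 1.0)

    def test_conservation_identities(self):
        labels = [("t%d" % i, "TP", 0) for i in range(7)]
        labels += [("f%d" % i, "FN", None) for i in range(3)]
        labels += [("b%d" % i, "FN_and_FP", 15) for i in range(2)]
        labels += [("x%d" % i, "FP", None) for i in range(4)]
        m = compute_metrics(_mc(labels), 100)
        # fn and fp totals both absorb the FN_and_FP persons
        assert m.tp + m.fn == m.n_registry_cases == 12
        assert m.tp + m.fp == m.n_identified == 13
        assert m.tn == 100 - 12 - 4


class TestWilson:
    def test_boundaries_are_exact(self):
        assert wilson_ci(0, 10)[0] == 0.0
        assert wilson_ci(10, 10)[1] == 1.0
        assert wilson_ci(0, 0) is None

    def test_normal_interval_option_is_symmetric(self):
        mc = _mc([(f"t{i}", "TP", 0) for i in range(10)]
                 + [(f"f{i}", "FN", None) for i in range(10)])
        m = compute_metrics(mc, 50, ci_method="normal")
        lo, hi = m.sensitivity_ci
        assert hi - m.sensitivity == pytest.approx(m.sensitivity - lo)

    def test_interval_contains_point_estimate(self):
        for k, n in [(1, 7), (5, 9), (2140, 2253), (50, 100)]:
            lo, hi = wilson_ci(k, n)
            assert lo <= k / n <= hi
            assert 0.0 <= lo and hi <= 1.0


class TestLagProfile:
    def test_hand_counted_fixture(self):
        mc = _mc([
            ("a", "TP", 0), ("b", "TP", 0), ("c", "TP", 2), ("d", "TP", -1),
        ], W=12)
        lp = lag_profile(mc)
        t = lp.table.set_index("offset_months")
        assert t.loc[0, "cum_sensitivity"] == 0.50
        assert t.loc[2, "cum_sensitivity"] == 0.75
        assert lp.negative_lag_fraction == 0.25

    def test_cumulative_series_conserve_overall_sensitivity(self):
        mc = _mc([
            ("a", "TP", 0), ("b", "TP", 5), ("c", "TP", -1),
            ("d", "FN", None), ("e", "FN_and_FP", 20), ("f", "FP", None),
        ], W=12)
        lp = lag_profile(mc)
        assert lp.table["cum_sensitivity"].is_monotonic_increasing
        assert lp.table["cum_ppv"].is_monotonic_increasing
        at_w = lp.table["cum_sensitivity"].iloc[-1]
        assert at_w + lp.negative_lag_fraction == pytest.approx(lp.overall_sensitivity)
        assert lp.overall_sensitivity == pytest.approx(3 / 5)


class TestMismatch:
    def _persons(self):
        return persons_frame([
            Person("m1", sd(2006, 3), 60),
            Person("m2", sd(2006, 3), 61, remoteness="non-metropolitan"),
            Person("n1", sd(2006, 3), 70, border_resident=True),
            Person("n2", sd(2006, 3), 71, border_resident=True, ses_quintile=1),
            Person("n3", sd(2006, 3), 72),
            Person("n4", sd(2006, 3), 73, death_date=sd(2008, 4, 1)),
        ])

    def _registry(self):
        return _registry([
            ("m1", "colorectal", "2008-01", "localised", 60.0),
            ("m2", "colorectal", "2008-02", "regional", 61.0),
            ("n1", "colorectal", "2008-03", "unknown", 70.0),
            ("n2", "colorectal", "2008-03", "unknown", 71.0),
            ("n3", "colorectal", "2008-03", "distant", 72.0),
            ("n4", "colorectal", "2008-04", "unknown", 73.0),
        ])

    def test_border_share_and_spread_distribution(self):
        mc = _mc([("m1", "TP", 0), ("m2", "TP", 1),
                  ("n1", "FN", None), ("n2", "FN", None),
                  ("n3", "FN", None), ("n4", "FN_and_FP", 14)])
        rep = stratify_mismatches(mc, self._persons(), self._registry())
        non = rep.groups["non_matches"]
        assert non.n == 4
        assert non.border_share == 0.5
        assert sum(non.spread_dist.values()) == pytest.approx(1.0)
        assert non.spread_dist["unknown"] == 0.75
        assert rep.groups["matches"].spread_dist["unknown"] == 0.0
        assert non.deaths_within[1] == 1

    def test_degenerate_group_is_flagged(self):
        mc = _mc([("m1", "TP", 0), ("m2", "TP", 0)])
        rep = stratify_mismatches(mc, self._persons(), self._registry())
        assert rep.groups["non_matches"].degenerate


class TestTriage:
    def test_rule_order_and_partition(self):
        full_reg = _registry([
            ("old", "colorectal", "1996-05", "unknown", 55.0),
        ])
        events = pd.DataFrame(
            [
                (0, "meta", "inpatient", "2008-02-01", "diagnosis", "ICD10", "C78.0", 0),
                (1, "old", "inpatient", "2008-02-01", "diagnosis", "ICD10", "C78.0", 0),
            ],
            columns=["record_id", "person_id", "source", "event_date",
                     "slot_role", "code_system", "code", "slot_index"],
        )
        mc = _mc([("old", "FP", None), ("meta", "FP", None), ("other", "FP", None)])
        tri = triage_death_fps(mc, events, full_reg, "colorectal")
        # registry-before-window outranks the secondary-malignancy code
        assert tri.counts == {"registry_prior_to_window": 1,
                              "possible_secondary": 1, "other_disease": 1}
        assert tri.total == 3

    def test_counts_partition_random_fp_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(3, 60))
            events = random_events(rng, n)
            full_reg = random_registry(rng, n)
            fps = [(f"P{i:03d}", "FP", None) for i in rng.integers(0, n, 15)]
            fps = list({p: (p, lab, lag) for p, lab, lag in fps}.values())
            tri = triage_death_fps(_mc(fps), events, full_reg, "colorectal")
            assert tri.total == len(fps)


class TestFollowupExtension:
    def test_incremental_case_percentages(self):
        base_reg = _registry(
            [(f"r{i}", "colorectal", "2009-06", "localised", 70.0) for i in range(1319)]
        )
        asc = AscertainmentSet(
            "x", {f"a{i}": sd(2012, 5, 1) for i in range(1549)}
        )
        baselines = pd.Series(
            "2007-01-01",
            index=[f"r{i}" for i in range(1319)] + [f"a{i}" for i in range(1549)],
        )
        rep = count_incremental_cases(asc, base_reg, "colorectal", sd(2010, 12), baselines)
        assert (rep.base_registry_cases, rep.added_cases) == (1319, 1549)
        assert rep.percent_increase == 117

        rep2 = count_incremental_cases(
            AscertainmentSet("x", {f"a{i}": sd(2012, 5, 1) for i in range(912)}),
            _registry([(f"r{i}", "lung", "2009-06", "localised", 70.0) for i in range(795)]),
            "lung", sd(2010, 12),
            pd.Series("2007-01-01",
                      index=[f"r{i}" for i in range(795)] + [f"a{i}" for i in range(912)]),
        )
        assert rep2.percent_increase == 115

    def test_pre_baseline_registry_cases_do_not_count_as_incident(self):
        reg = _registry([("r0", "colorectal", "2006-06", "localised", 70.0)])
        baselines = pd.Series({"r0": "2007-01-01"})
        rep = count_incremental_cases(
            AscertainmentSet("x", {}), reg, "colorectal", sd(2010, 12), baselines
        )
        assert rep.base_registry_cases == 0
        assert rep.percent_increase is None

    def test_date_agnostic_ppv_reconstruction(self):
        # 3747 identified; 332 without an in-window registry record, of whom
        # 123 have a prior-period record -> (3747-332+123)/3747
        asc = AscertainmentSet("x", {f"p{i}": sd(2008, 1) for i in range(3747)})
        rows = [(f"p{i}", "colorectal", "2008-01", "localised", 70.0) for i in range(3415)]
        rows += [(f"p{3415+i}", "colorectal", "1999-05", "localised", 60.0)
                 for i in range(123)]
        full = _registry(rows)
        ppv = date_agnostic_ppv(asc, full, "colorectal")
        assert round(100 * ppv) == 94
        assert date_agnostic_ppv(AscertainmentSet("x", {}), full, "colorectal") is None

    def test_date_agnostic_ppv_bounds_windowed_ppv(self):
        rng = np.random.default_rng(23)
        from ascertain import extract_indicator
        from .conftest import CRC_DX_FOR_TESTS
        for _ in range(10):
            n = int(rng.integers(10, 120))
            events = random_events(rng, n)
            registry = random_registry(rng, n)
            asc = extract_indicator(events, CRC_DX_FOR_TESTS, WINDOW)
            if len(asc) == 0:
                continue
            agnostic = date_agnostic_ppv(asc, registry, "colorectal")
            for W in (0, 3, 12):
                mc = classify_cases(asc, registry, "colorectal", WINDOW, W)
                m = compute_metrics(mc, 300)
                assert agnostic >= m.ppv - 1e-12
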