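"""Validation of surrogate case ascertainment against a gold-standard registry.

The unit of analysis is the *person*, one cancer type at a time.  A person
with a registry diagnosis inside the evaluation window is a true positive
when the indicator's first-occurrence date falls within ±W months of the
registry diagnosis month; a registry case ascertained only *outside* ±W
counts as a false negative for sensitivity and simultaneously as a
non-true-positive identification for PPV (label ``FN_and_FP``) — the only
reading under which the sensitivity and PPV denominators both stay honest.

    sensitivity = TP / (registry cases in window)
    specificity = TN / (evaluated persons without a registry case)
    PPV         = TP / (persons identified by the indicator in window)

Confidence intervals are Wilson score intervals by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import SPREAD_CATEGORIES, month_idx_of
from .dates import StudyDate
from .indicators import AscertainmentSet

__all__ = [
    "MatchClassification", "ValidityMetrics", "LagProfile", "MismatchReport",
    "DiscordanceTriage", "IncrementReport",
    "classify_cases", "compute_metrics", "wilson_ci", "lag_profile",
    "stratify_mismatches", "triage_death_fps", "count_incremental_cases",
    "date_agnostic_ppv",
]

SECONDARY_MALIGNANCY_PREFIXES = ("C77", "C78", "C79")


@dataclass
class MatchClassification:
    """Per-person TP/FN/FP labels for one indicator, cancer type and window.

    ``labels`` has one row per person who is a registry case in the window
    or was ascertained (everyone else is an implicit true negative):
    columns ``person_id``, ``label`` in {TP, FN, FP, FN_and_FP},
    ``lag_months`` (ascertainment − registry month; NA when either side is
    missing), ``dx_month_idx`` and ``asc_month_idx``.
    """

    cancer_type: str
    indicator: str
    window_months: int
    eval_window: tuple[StudyDate, StudyDate]
    labels: pd.DataFrame

    def count(self, *labels: str) -> int:
        return int(self.labels["label"].isin(labels).sum())

    @property
    def n_registry_cases(self) -> int:
        return self.count("TP", "FN", "FN_and_FP")

    @property
    def n_identified(self) -> int:
        return self.count("TP", "FP", "FN_and_FP")


def _registry_cases(
    registry: pd.DataFrame, cancer_type: str, lo: int | None, hi: int | None
) -> pd.Series:
    """Earliest diagnosis month index per person for one cancer type."""
    sub = registry[registry["cancer_type"] == cancer_type]
    if len(sub) == 0:
        return pd.Series(dtype=float)
    m = month_idx_of(sub["diagnosis_date"])
    keep = np.ones(len(sub), dtype=bool)
    if lo is not None:
        keep &= m >= lo
    if hi is not None:
        keep &= m <= hi
    sub = pd.DataFrame({"person_id": sub["person_id"].to_numpy()[keep], "m": m[keep]})
    return sub.groupby("person_id")["m"].min()


def classify_cases(
    asc: AscertainmentSet,
    registry: pd.DataFrame,
    cancer_type: str,
    eval_window: tuple[StudyDate, StudyDate],
    window_months: int = 12,
) -> MatchClassification:
    """Label every registry case and every ascertained person.

    A person's registry diagnosis is their *earliest* registry record of
    ``cancer_type`` inside ``eval_window``; lag is computed at month
    granularity (days never enter the comparison).
    """
    if window_months < 0:
        raise ValueError("window_months must be >= 0")
    lo, hi = eval_window[0].month_index, eval_window[1].month_index
    dx = _registry_cases(registry, cancer_type, lo, hi)

    rows = []
    for pid, dxm in dx.items():
        first = asc.cases.get(pid)
        if first is None:
            rows.append((pid, "FN", pd.NA, int(dxm), pd.NA))
        else:
            lag = first.month_index - int(dxm)
            label = "TP" if abs(lag) <= window_months else "FN_and_FP"
            rows.append((pid, label, lag, int(dxm), first.month_index))
    case_ids = set(dx.index)
    for pid in sorted(asc.cases):
        if pid not in case_ids:
            rows.append((pid, "FP", pd.NA, pd.NA, asc.cases[pid].month_index))

    labels = pd.DataFrame(
        rows, columns=["person_id", "label", "lag_months", "dx_month_idx", "asc_month_idx"]
    )
    labels["lag_months"] = labels["lag_months"].astype("Int64")
    labels["dx_month_idx"] = labels["dx_month_idx"].astype("Int64")
    labels["asc_month_idx"] = labels["asc_month_idx"].astype("Int64")
    return MatchClassification(
        cancer_type=cancer_type,
        indicator=asc.name,
        window_months=window_months,
        eval_window=eval_window,
        labels=labels,
    )


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float] | None:
    """Wilson score interval for a binomial proportion; ``None`` when n = 0."""
    if n == 0:
        return None
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    # the score interval's bounds are exactly 0/1 at the boundaries; protect
    # them from floating-point wobble
    lo = 0.0 if k == 0 else float(max(0.0, lo))
    hi = 1.0 if k == n else float(min(1.0, hi))
    return (lo, hi)


def _normal_ci(k: int, n: int, level: float) -> tuple[float, float] | None:
    if n == 0:
        return None
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="normal")
    return (float(max(0.0, lo)), float(min(1.0, hi)))


@dataclass
class ValidityMetrics:
    """Diagnostic accuracy of one indicator against the registry."""

    cancer_type: str
    indicator: str
    window_months: int
    n_evaluated: int
    n_registry_cases: int
    n_identified: int
    tp: int
    fn: int
    fp: int
    fn_and_fp: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    ppv_ci: tuple[float, float] | None

    def as_row(self) -> dict:
        def pct(x):
            return None if x is None else round(100 * x, 6)

        row = {
            "cancer_type": self.cancer_type,
            "indicator": self.indicator,
            "window_months": self.window_months,
            "n_evaluated": self.n_evaluated,
            "n_registry_cases": self.n_registry_cases,
            "n_identified": self.n_identified,
            "tp": self.tp, "fn": self.fn, "fp": self.fp,
            "fn_and_fp": self.fn_and_fp, "tn": self.tn,
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "ppv_pct": pct(self.ppv),
        }
        for nm, ci in (
            ("sensitivity", self.sensitivity_ci),
            ("specificity", self.specificity_ci),
            ("ppv", self.ppv_ci),
        ):
            row[f"{nm}_ci_low_pct"] = pct(ci[0]) if ci else None
            row[f"{nm}_ci_high_pct"] = pct(ci[1]) if ci else None
        return row


def compute_metrics(
    mc: MatchClassification, n_evaluated: int, ci_method: str = "wilson",
    level: float = 0.95,
) -> ValidityMetrics:
    """Point estimates and confidence intervals from a classification.

    ``n_evaluated`` is the eligible cohort size; true negatives are the
    persons neither registry cases nor ascertained, so they never need to
    be materialised.  PPV is ``None`` when nothing was identified.
    """
    tp = mc.count("TP")
    fn = mc.count("FN")
    fp = mc.count("FP")
    fnfp = mc.count("FN_and_FP")
    n_registry = tp + fn + fnfp
    n_identified = tp + fp + fnfp
    n_non_cases = n_evaluated - n_registry
    tn = n_non_cases - fp
    if tn < 0:
        raise ValueError("n_evaluated smaller than the number of labelled persons")

    ci = wilson_ci if ci_method == "wilson" else lambda k, n, level=level: _normal_ci(k, n, level)
    sens = tp / n_registry if n_registry else None
    spec = tn / n_non_cases if n_non_cases else None
    ppv = tp / n_identified if n_identified else None
    return ValidityMetrics(
        cancer_type=mc.cancer_type,
        indicator=mc.indicator,
        window_months=mc.window_months,
        n_evaluated=n_evaluated,
        n_registry_cases=n_registry,
        n_identified=n_identified,
        tp=tp, fn=fn + fnfp, fp=fp + fnfp, fn_and_fp=fnfp, tn=tn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        sensitivity_ci=ci(tp, n_registry, level=level) if n_registry else None,
        specificity_ci=ci(tn, n_non_cases, level=level) if n_non_cases else None,
        ppv_ci=ci(tp, n_identified, level=level) if n_identified else None,
    )


@dataclass
class LagProfile:
    """Cumulative sensitivity/PPV by months elapsed since the registry date.

    ``table`` has one row per offset m = 0..W with the cumulative
    sensitivity and PPV counting true positives with lag in [0, m];
    cases first ascertained *before* the registry month are reported
    separately as ``negative_lag_fraction`` (of registry cases), so the
    value at m = W plus that fraction equals overall sensitivity.
    """

    cancer_type: str
    indicator: str
    window_months: int
    table: pd.DataFrame
    negative_lag_fraction: float
    overall_sensitivity: float


def lag_profile(mc: MatchClassification) -> LagProfile:
    W = mc.window_months
    lags = mc.labels.loc[mc.labels["label"] == "TP", "lag_months"].astype(int)
    n_registry = mc.n_registry_cases
    n_identified = mc.n_identified
    rows = []
    for m in range(W + 1):
        k = int(((lags >= 0) & (lags <= m)).sum())
        rows.append(
            {
                "offset_months": m,
                "tp_cumulative": k,
                "cum_sensitivity": k / n_registry if n_registry else np.nan,
                "cum_ppv": k / n_identified if n_identified else np.nan,
            }
        )
    neg = int((lags < 0).sum())
    return LagProfile(
        cancer_type=mc.cancer_type,
        indicator=mc.indicator,
        window_months=W,
        table=pd.DataFrame(rows),
        negative_lag_fraction=neg / n_registry if n_registry else np.nan,
        overall_sensitivity=len(lags) / n_registry if n_registry else np.nan,
    )


@dataclass
class GroupSummary:
    n: int
    spread_dist: dict = field(default_factory=dict)
    remoteness_dist: dict = field(default_factory=dict)
    ses_low_share: float | None = None  # two most disadvantaged quintiles
    border_share: float | None = None
    age_median: float | None = None
    age_iqr: tuple[float, float] | None = None
    deaths_within: dict = field(default_factory=dict)  # months -> count
    degenerate: bool = False


@dataclass
class MismatchReport:
    """Characteristics of registry cases the indicator did vs did not match."""

    cancer_type: str
    indicator: str
    groups: dict  # {"matches": GroupSummary, "non_matches": GroupSummary}


def _group_summary(
    ids: list[str], persons: pd.DataFrame, reg: pd.DataFrame, death_within: tuple[int, ...]
) -> GroupSummary:
    if not ids:
        return GroupSummary(n=0, degenerate=True)
    p = persons[persons["person_id"].isin(ids)]
    r = reg[reg["person_id"].isin(ids)].drop_duplicates("person_id")
    out = GroupSummary(n=len(ids))

    if r["spread_of_disease"].notna().any():
        counts = r["spread_of_disease"].value_counts()
        total = counts.sum()
        out.spread_dist = {
            c: float(counts.get(c, 0) / total) for c in SPREAD_CATEGORIES
        }
    else:
        warnings.warn("spread_of_disease wholly missing; stratum omitted")
    if p["remoteness"].notna().any():
        counts = p["remoteness"].value_counts()
        out.remoteness_dist = {k: float(v / counts.sum()) for k, v in sorted(counts.items())}
    else:
        warnings.warn("remoteness wholly missing; stratum omitted")
    ses = pd.to_numeric(p["ses_quintile"], errors="coerce")
    if ses.notna().any():
        out.ses_low_share = float((ses <= 2).sum() / ses.notna().sum())
    else:
        warnings.warn("ses_quintile wholly missing; stratum omitted")
    if p["border_resident"].notna().any():
        out.border_share = float(p["border_resident"].astype(bool).mean())
    age = pd.to_numeric(r["age_at_diagnosis"], errors="coerce")
    if age.notna().any():
        out.age_median = float(age.median())
        out.age_iqr = (float(age.quantile(0.25)), float(age.quantile(0.75)))

    dxm = month_idx_of(r["diagnosis_date"])
    dm = pd.Series(
        month_idx_of(persons["death_date"]), index=persons["person_id"].to_numpy()
    ).reindex(r["person_id"]).to_numpy()
    for k in death_within:
        with np.errstate(invalid="ignore"):
            out.deaths_within[k] = int(np.nansum((dm - dxm) <= k))
    return out


def stratify_mismatches(
    mc: MatchClassification,
    persons: pd.DataFrame,
    registry: pd.DataFrame,
    death_within: tuple[int, ...] = (1, 12),
) -> MismatchReport:
    """Compare registry cases matched within ±W against those missed.

    Interstate leakage shows up here: border residents hospitalised out of
    state are over-represented among non-matches.
    """
    lab = mc.labels
    matched = lab.loc[lab["label"] == "TP", "person_id"].tolist()
    unmatched = lab.loc[lab["label"].isin(["FN", "FN_and_FP"]), "person_id"].tolist()
    lo, hi = mc.eval_window[0].month_index, mc.eval_window[1].month_index
    reg = registry[registry["cancer_type"] == mc.cancer_type].copy()
    m = month_idx_of(reg["diagnosis_date"])
    reg = reg[(m >= lo) & (m <= hi)]
    reg = reg.sort_values("diagnosis_date").drop_duplicates("person_id", keep="first")
    return MismatchReport(
        cancer_type=mc.cancer_type,
        indicator=mc.indicator,
        groups={
            "matches": _group_summary(matched, persons, reg, death_within),
            "non_matches": _group_summary(unmatched, persons, reg, death_within),
        },
    )


@dataclass
class DiscordanceTriage:
    """Explanation categories for death-record cases absent from the registry."""

    cancer_type: str
    counts: dict  # category -> count
    assignments: pd.DataFrame  # person_id, category

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


def triage_death_fps(
    mc: MatchClassification,
    events: pd.DataFrame,
    registry_full_history: pd.DataFrame,
    cancer_type: str,
) -> DiscordanceTriage:
    """Assign each pure false positive to its most likely explanation.

    Categories, in rule order: ``registry_prior_to_window`` (a registry
    record of the cancer type before the evaluation window — a prevalent,
    not incident, case), ``possible_secondary`` (any linked record carries
    a secondary-malignancy code C77–C79), else ``other_disease``.
    """
    lo = mc.eval_window[0].month_index
    fp_ids = mc.labels.loc[mc.labels["label"] == "FP", "person_id"].tolist()

    prior = _registry_cases(registry_full_history, cancer_type, None, lo - 1)
    prior_ids = set(prior.index)

    ev = events[events["person_id"].isin(fp_ids)]
    codes = ev["code"].astype("string").str.upper().str.replace(".", "", regex=False)
    sec_mask = np.zeros(len(ev), dtype=bool)
    for p in SECONDARY_MALIGNANCY_PREFIXES:
        sec_mask |= codes.str.startswith(p).fillna(False).to_numpy()
    secondary_ids = set(ev.loc[sec_mask, "person_id"])

    rows = []
    for pid in sorted(fp_ids):
        if pid in prior_ids:
            cat = "registry_prior_to_window"
        elif pid in secondary_ids:
            cat = "possible_secondary"
        else:
            cat = "other_disease"
        rows.append((pid, cat))
    assignments = pd.DataFrame(rows, columns=["person_id", "category"])
    counts = {
        c: int((assignments["category"] == c).sum())
        for c in ("registry_prior_to_window", "possible_secondary", "other_disease")
    }
    return DiscordanceTriage(cancer_type=cancer_type, counts=counts, assignments=assignments)


@dataclass
class IncrementReport:
    """Extra incident cases gained by extending ascertainment past registry coverage."""

    cancer_type: str
    base_registry_cases: int
    added_cases: int
    percent_increase: int | None


def count_incremental_cases(
    asc_extended: AscertainmentSet,
    registry: pd.DataFrame,
    cancer_type: str,
    registry_end: StudyDate,
    baseline_dates: pd.Series,
) -> IncrementReport:
    """Count surrogate-only cases appearing after the registry's last month.

    ``base`` is the number of *incident* registry cases — diagnosed after
    the person's baseline and no later than ``registry_end``.  ``added``
    counts persons first ascertained after ``registry_end`` who never
    appear in the registry at all.  ``baseline_dates`` maps person_id to
    baseline date (ISO string or StudyDate).
    """
    end_idx = registry_end.month_index
    base_m = baseline_dates.map(
        lambda v: v.month_index if isinstance(v, StudyDate) else StudyDate.parse(v).month_index
    )
    dx = _registry_cases(registry, cancer_type, None, end_idx)
    aligned = base_m.reindex(dx.index)
    base = int((dx > aligned).sum())

    ever = set(registry.loc[registry["cancer_type"] == cancer_type, "person_id"])
    added = sum(
        1
        for pid, d in asc_extended.cases.items()
        if d.month_index > end_idx and pid not in ever
    )
    pct = round(100 * added / base) if base else None
    return IncrementReport(
        cancer_type=cancer_type,
        base_registry_cases=base,
        added_cases=added,
        percent_increase=pct,
    )


def date_agnostic_ppv(
    asc: AscertainmentSet, registry_full_history: pd.DataFrame, cancer_type: str
) -> float | None:
    """Share of ascertained persons with *any* registry record of the type.

    Ignoring dates credits the indicator for prevalent cases it re-detects;
    the gap between this and the windowed PPV measures how much of the
    apparent false-positive load is really old disease.
    """
    if len(asc) == 0:
        return None
    ever = set(registry_full_history.loc[
        registry_full_history["cancer_type"] == cancer_type, "person_id"
    ])
    hits = sum(1 for pid in asc.cases if pid in ever)
    return hits / len(asc)
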