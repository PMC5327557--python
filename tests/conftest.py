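"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive everything per person with plain Python
scans so they share no code path with the vectorised implementation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ascertain import (
    Cohort,
    EventRecord,
    Person,
    RegistryDiagnosis,
    StudyDate,
    events_frame,
    persons_frame,
    registry_frame,
)
from ascertain.indicators import IndicatorDefinition, normalize_code
from ascertain.synthetic import LagDistribution, SyntheticCohortConfig, default_config


def sd(year, month, day=None) -> StudyDate:
    return StudyDate(year, month, day)


WINDOW = (sd(2006, 2), sd(2010, 12))

CRC_DX_FOR_TESTS = IndicatorDefinition(
    name="apdc_dx", source="inpatient", slot_role="diagnosis",
    code_system="ICD10", codes=("C18", "C19", "C20"),
)


def noiseless_config(n_persons: int = 2000, seed: int = 0) -> SyntheticCohortConfig:
    """Every true case coded in its diagnosis month; no contamination, no deaths."""
    base = default_config(n_persons=n_persons, seed=seed)
    cancers = tuple(
        dataclasses.replace(
            cm,
            p_code=1.0,
            lag=LagDistribution.from_dict({0: 1.0}),
            unknown_spread_penalty=1.0,
            prevalent_fraction=0.0,
            recode_probability=0.0,
            miscode_monthly=0.0,
            case_fatality_monthly=0.0,
            noncase_death_cause_fp=0.0,
            monthly_incidence=2e-3,
        )
        for cm in base.cancers
    )
    return dataclasses.replace(
        base,
        cancers=cancers,
        border_capture_penalty=1.0,
        background_mortality_monthly=0.0,
    )


@pytest.fixture
def small_cohort() -> Cohort:
    """Three persons, a handful of events, one registry case per cancer type."""
    persons = persons_frame(
        [
            Person("A", sd(2006, 3, 10), 60, ses_quintile=1, remoteness="non-metropolitan"),
            Person("B", sd(2007, 1, 5), 52, border_resident=True),
            Person("C", sd(2006, 8, 20), 70, death_date=sd(2009, 6, 2)),
        ]
    )
    events = events_frame(
        [
            EventRecord("A", "inpatient", sd(2007, 4, 3),
                        (("diagnosis", "ICD10", "C18.2"), ("procedure", "ACHI", "32000"))),
            EventRecord("A", "inpatient", sd(2007, 7, 9),
                        (("diagnosis", "ICD10", "Z85.0"),)),
            EventRecord("B", "emergency", sd(2008, 2, 14),
                        (("diagnosis", "ICD10", "C34.1"),)),
            EventRecord("C", "inpatient", sd(2008, 11, 1),
                        (("diagnosis", "ICD10", "C78.5"),)),
            EventRecord("C", "death", sd(2009, 6, 2),
                        (("cause_of_death", "ICD10", "I21.9"),
                         ("cause_of_death", "ICD10", "C18.9"))),
        ]
    )
    registry = registry_frame(
        [
            RegistryDiagnosis("A", "colorectal", sd(2007, 4), "localised", 61.1),
            RegistryDiagnosis("B", "lung", sd(2008, 2), "distant", 53.1),
        ]
    )
    coverage = {
        "inpatient": (sd(2001, 7), sd(2014, 6)),
        "emergency": (sd(2005, 1), sd(2014, 12)),
        "claims_medical": (sd(2004, 6), sd(2014, 12)),
        "claims_pharma": (sd(2004, 6), sd(2014, 12)),
        "death": (sd(2006, 1), sd(2012, 12)),
    }
    return Cohort(persons=persons, events=events, registry=registry, coverage=coverage).validate()


# --- brute-force oracles -------------------------------------------------

def brute_extract(events: pd.DataFrame, ind: IndicatorDefinition, window) -> dict:
    """Per-person, per-row scan of the whole events table."""
    lo, hi = window[0].month_index, window[1].month_index
    exact = {normalize_code(c) for c in ind.exact_codes}
    if not ind.prefix:
        exact |= {normalize_code(c) for c in ind.codes}
    prefixes = [normalize_code(c) for c in ind.codes] if ind.prefix else []
    best: dict[str, tuple] = {}
    for row in events.itertuples():
        if row.source != ind.source or row.slot_role != ind.slot_role:
            continue
        if (ind.source == "death" and ind.cause_position == "underlying_only"
                and row.slot_index != 0):
            continue
        if row.code_system != ind.code_system:
            continue
        c = normalize_code(row.code)
        if not (c in exact or any(c.startswith(p) for p in prefixes)):
            continue
        d = StudyDate.parse(row.event_date)
        if not (lo <= d.month_index <= hi):
            continue
        key = (d.month_index, 0 if d.day is not None else 1, d.day or 0,
               row.record_id, row.slot_index)
        if row.person_id not in best or key < best[row.person_id][0]:
            best[row.person_id] = (key, d)
    return {p: d for p, (_, d) in best.items()}


def brute_composite(events, tree, definitions, window, anchor) -> dict:
    """Truth-table evaluation of a parsed expression, person by person."""
    leaf_sets = {name: brute_extract(events, definitions[name], window)
                 for name in _leaves(tree)}
    persons = set().union(*leaf_sets.values()) if leaf_sets else set()

    def holds(node, pid):
        if node[0] == "leaf":
            return pid in leaf_sets[node[1]]
        if node[0] == "and":
            return all(holds(s, pid) for s in node[1])
        return any(holds(s, pid) for s in node[1])

    def date_of(node, pid):
        if node[0] == "leaf":
            return leaf_sets[node[1]].get(pid)
        if node[0] == "or":
            dates = [date_of(s, pid) for s in node[1]]
            dates = [d for d in dates if d is not None]
            return min(dates, key=lambda d: d.sort_key()) if dates else None
        # AND: dated by the branch containing the anchor, else the first branch
        for s in node[1]:
            if anchor in _leaves(s):
                return date_of(s, pid)
        return date_of(node[1][0], pid)

    return {pid: date_of(tree, pid) for pid in persons if holds(tree, pid)}


def _leaves(node):
    if node[0] == "leaf":
        return [node[1]]
    out = []
    for s in node[1]:
        out.extend(_leaves(s))
    return out


def brute_classify(asc_cases: dict, registry: pd.DataFrame, cancer: str,
                   window, W: int) -> dict:
    """Person-by-person label assignment from first principles."""
    lo, hi = window[0].month_index, window[1].month_index
    dx: dict[str, int] = {}
    for row in registry.itertuples():
        if row.cancer_type != cancer:
            continue
        m = StudyDate.parse(row.diagnosis_date).month_index
        if lo <= m <= hi and (row.person_id not in dx or m < dx[row.person_id]):
            dx[row.person_id] = m
    labels = {}
    for pid, m in dx.items():
        if pid not in asc_cases:
            labels[pid] = "FN"
        elif abs(asc_cases[pid].month_index - m) <= W:
            labels[pid] = "TP"
        else:
            labels[pid] = "FN_and_FP"
    for pid in asc_cases:
        if pid not in dx:
            labels[pid] = "FP"
    return labels


# --- randomised fixture factory ------------------------------------------

CODE_POOL = [
    ("diagnosis", "ICD10", "C18.0"), ("diagnosis", "ICD10", "C18.9"),
    ("diagnosis", "ICD10", "C19"), ("diagnosis", "ICD10", "C20.8"),
    ("diagnosis", "ICD10", "C34.1"), ("diagnosis", "ICD10", "C78.5"),
    ("diagnosis", "ICD10", "Z85.0"), ("diagnosis", "ICD10", "K57.9"),
    ("diagnosis", "ICD9", "153.9"), ("procedure", "ACHI", "32000"),
    ("procedure", "ACHI", "96199"), ("item", "MBS_ITEM", "32024"),
    ("item", "PBS_ITEM", "FLUOROURACIL"),
    ("cause_of_death", "ICD10", "C18.9"), ("cause_of_death", "ICD10", "I21.9"),
]
SOURCE_ROLES = {
    "inpatient": ("diagnosis", "procedure"),
    "emergency": ("diagnosis",),
    "claims_medical": ("item",),
    "claims_pharma": ("item",),
    "death": ("cause_of_death",),
}


def random_events(rng: np.random.Generator, n_persons: int) -> pd.DataFrame:
    """A messy random events table: mixed sources, slots, days and months."""
    rows = []
    rid = 0
    lo = WINDOW[0].month_index - 6
    hi = WINDOW[1].month_index + 6
    for _ in range(int(rng.integers(1, 4 * n_persons))):
        pid = f"P{rng.integers(n_persons):03d}"
        source = list(SOURCE_ROLES)[rng.integers(len(SOURCE_ROLES))]
        m = int(rng.integers(lo, hi + 1))
        day = int(rng.integers(1, 29)) if rng.random() < 0.7 else None
        date = StudyDate(m // 12, m % 12 + 1, day).isoformat()
        n_codes = int(rng.integers(1, 4))
        slot = 0
        for _ in range(n_codes):
            role, system, code = CODE_POOL[rng.integers(len(CODE_POOL))]
            if role not in SOURCE_ROLES[source]:
                role = SOURCE_ROLES[source][0]
            rows.append((rid, pid, source, date, role, system, code, slot))
            slot += 1
        rid += 1
    return pd.DataFrame(
        rows,
        columns=["record_id", "person_id", "source", "event_date",
                 "slot_role", "code_system", "code", "slot_index"],
    )


def random_registry(rng: np.random.Generator, n_persons: int) -> pd.DataFrame:
    rows = []
    lo = WINDOW[0].month_index - 24
    hi = WINDOW[1].month_index + 6
    for _ in range(int(rng.integers(0, n_persons))):
        pid = f"P{rng.integers(n_persons):03d}"
        m = int(rng.integers(lo, hi + 1))
        cancer = "colorectal" if rng.random() < 0.6 else "lung"
        rows.append((pid, cancer, StudyDate.from_month_index(m).isoformat(),
                     "unknown", 70.0))
    return pd.DataFrame(
        rows,
        columns=["person_id", "cancer_type", "diagnosis_date",
                 "spread_of_disease", "age_at_diagnosis"],
    )
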