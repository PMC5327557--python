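"""Linked-cohort containers and eligibility filtering.

A :class:`Cohort` bundles three pandas tables — persons, coded events and
gold-standard registry diagnoses — together with per-source coverage windows
(administrative collections start and stop on different dates).  Events are
stored *long*: one row per code slot, so a hospital admission with three
diagnosis codes and one procedure code occupies four rows sharing a
``record_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dates import StudyDate
from .errors import ReferentialError, ValidationError

SOURCES = ("inpatient", "emergency", "claims_medical", "claims_pharma", "death")
SLOT_ROLES = ("diagnosis", "procedure", "item", "cause_of_death")
CODE_SYSTEMS = ("ICD10", "ICD9", "SNOMED", "ACHI", "MBS_ITEM", "PBS_ITEM")

#: maximum code slots per record, keyed by (source, slot_role)
SLOT_CAPS = {
    ("inpatient", "diagnosis"): 55,
    ("inpatient", "procedure"): 50,
    ("death", "cause_of_death"): 21,  # 1 underlying + up to 20 contributing
}

PERSON_COLUMNS = [
    "person_id", "baseline_date", "age_at_baseline", "sex", "ses_quintile",
    "remoteness", "border_resident", "death_date",
]
EVENT_COLUMNS = [
    "record_id", "person_id", "source", "event_date", "slot_role",
    "code_system", "code", "slot_index",
]
REGISTRY_COLUMNS = [
    "person_id", "cancer_type", "diagnosis_date", "spread_of_disease",
    "age_at_diagnosis",
]

SPREAD_CATEGORIES = ("localised", "regional", "distant", "unknown")


def month_idx_of(dates: pd.Series) -> np.ndarray:
    """Vectorised month index of ISO ``YYYY-MM[-DD]`` strings (NaN for missing)."""
    s = dates.astype("string")
    year = pd.to_numeric(s.str.slice(0, 4), errors="coerce")
    month = pd.to_numeric(s.str.slice(5, 7), errors="coerce")
    return (12 * year + month - 1).to_numpy(dtype=float)


def day_of(dates: pd.Series) -> np.ndarray:
    """Vectorised day component (NaN when the date is month-precision or missing)."""
    s = dates.astype("string")
    return pd.to_numeric(s.str.slice(8, 10), errors="coerce").to_numpy(dtype=float)


def _check_dates(df: pd.DataFrame, col: str, *, allow_missing: bool, label: str) -> None:
    s = df[col]
    missing = s.isna() | (s.astype("string").str.len() == 0)
    if missing.any() and not allow_missing:
        rows = df.index[missing][:5].tolist()
        raise ValidationError(f"{label}.{col}: missing date in rows {rows}")
    v = s[~missing].astype("string")
    is_month = v.str.fullmatch(r"\d{4}-(0[1-9]|1[0-2])")
    full = v[~is_month.fillna(False)]
    ok_full = pd.Series(True, index=full.index)
    if len(full):
        shaped = full.str.fullmatch(r"\d{4}-\d{2}-\d{2}").fillna(False)
        parsed = pd.to_datetime(full.where(shaped), format="%Y-%m-%d", errors="coerce")
        ok_full = shaped & parsed.notna()
    bad_idx = list(full.index[~ok_full][:5])
    if bad_idx:
        raise ValidationError(f"{label}.{col}: unparseable dates in rows {bad_idx}")


@dataclass(frozen=True)
class Person:
    """Convenience record for building small cohorts by hand."""

    person_id: str
    baseline_date: StudyDate
    age_at_baseline: float
    sex: str = "female"
    ses_quintile: int = 3
    remoteness: str = "metropolitan"
    border_resident: bool = False
    death_date: StudyDate | None = None


@dataclass(frozen=True)
class EventRecord:
    """One dated, coded observation from one surrogate source.

    ``codes`` is a sequence of ``(slot_role, code_system, code)`` triples;
    slot order is preserved (slot 0 of a death record is the underlying
    cause).
    """

    person_id: str
    source: str
    event_date: StudyDate
    codes: tuple[tuple[str, str, str], ...]


@dataclass(frozen=True)
class RegistryDiagnosis:
    person_id: str
    cancer_type: str
    diagnosis_month: StudyDate
    spread_of_disease: str = "unknown"
    age_at_diagnosis: float = float("nan")


def persons_frame(persons: list[Person]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": [p.person_id for p in persons],
            "baseline_date": [p.baseline_date.isoformat() for p in persons],
            "age_at_baseline": [p.age_at_baseline for p in persons],
            "sex": [p.sex for p in persons],
            "ses_quintile": [p.ses_quintile for p in persons],
            "remoteness": [p.remoteness for p in persons],
            "border_resident": [p.border_resident for p in persons],
            "death_date": [
                p.death_date.isoformat() if p.death_date is not None else pd.NA
                for p in persons
            ],
        },
        columns=PERSON_COLUMNS,
    )


def events_frame(records: list[EventRecord]) -> pd.DataFrame:
    rows = []
    for rid, rec in enumerate(records):
        for slot, (role, system, code) in enumerate(rec.codes):
            rows.append(
                (rid, rec.person_id, rec.source, rec.event_date.isoformat(),
                 role, system, code, slot)
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def registry_frame(diagnoses: list[RegistryDiagnosis]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": [d.person_id for d in diagnoses],
            "cancer_type": [d.cancer_type for d in diagnoses],
            "diagnosis_date": [d.diagnosis_month.isoformat() for d in diagnoses],
            "spread_of_disease": [d.spread_of_disease for d in diagnoses],
            "age_at_diagnosis": [d.age_at_diagnosis for d in diagnoses],
        },
        columns=REGISTRY_COLUMNS,
    )


@dataclass
class Cohort:
    """Persons, surrogate events and registry records for one linked cohort."""

    persons: pd.DataFrame
    events: pd.DataFrame
    registry: pd.DataFrame
    coverage: dict[str, tuple[StudyDate, StudyDate]] = field(default_factory=dict)
    #: row-level messages for input rows rejected during reading
    diagnostics: list = field(default_factory=list)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def validate(self) -> "Cohort":
        """Check all container invariants; raises on the first violation."""
        for name, df, cols in (
            ("persons", self.persons, PERSON_COLUMNS),
            ("events", self.events, EVENT_COLUMNS),
            ("registry", self.registry, REGISTRY_COLUMNS),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValidationError(f"{name} table missing columns {missing}")

        if self.persons["person_id"].duplicated().any():
            dup = self.persons.loc[self.persons["person_id"].duplicated(), "person_id"]
            raise ValidationError(f"duplicate person_id values: {dup.head().tolist()}")
        if (self.persons["age_at_baseline"] < 0).any():
            raise ValidationError("negative age_at_baseline")

        _check_dates(self.persons, "baseline_date", allow_missing=False, label="persons")
        _check_dates(self.persons, "death_date", allow_missing=True, label="persons")
        _check_dates(self.events, "event_date", allow_missing=False, label="events")
        _check_dates(self.registry, "diagnosis_date", allow_missing=False, label="registry")

        if day_of(self.registry["diagnosis_date"]).size and not np.isnan(
            day_of(self.registry["diagnosis_date"])
        ).all():
            raise ValidationError("registry diagnosis dates must be month-precision (YYYY-MM)")

        dm = month_idx_of(self.persons["death_date"])
        bm = month_idx_of(self.persons["baseline_date"])
        bad = ~np.isnan(dm) & (dm < bm)
        if bad.any():
            who = self.persons.loc[bad, "person_id"].head().tolist()
            raise ValidationError(f"death_date before baseline_date for {who}")

        known = set(self.persons["person_id"])
        for label, df in (("events", self.events), ("registry", self.registry)):
            orphan = ~df["person_id"].isin(known)
            if orphan.any():
                rows = df.index[orphan][:5].tolist()
                who = df.loc[orphan, "person_id"].head().tolist()
                raise ReferentialError(
                    f"{label} rows {rows} reference unknown persons {who}"
                )

        bad_src = ~self.events["source"].isin(SOURCES)
        if bad_src.any():
            raise ValidationError(
                f"unknown event source values: {sorted(self.events.loc[bad_src, 'source'].unique())}"
            )
        bad_role = ~self.events["slot_role"].isin(SLOT_ROLES)
        if bad_role.any():
            raise ValidationError(
                f"unknown slot_role values: {sorted(self.events.loc[bad_role, 'slot_role'].unique())}"
            )
        bad_sys = ~self.events["code_system"].isin(CODE_SYSTEMS)
        if bad_sys.any():
            raise ValidationError(
                f"unknown code_system values: {sorted(self.events.loc[bad_sys, 'code_system'].unique())}"
            )

        if len(self.events):
            counts = self.events.groupby(
                ["record_id", "source", "slot_role"], sort=False
            ).size()
            for (src, role), cap in SLOT_CAPS.items():
                sel = counts.loc[
                    (counts.index.get_level_values("source") == src)
                    & (counts.index.get_level_values("slot_role") == role)
                ]
                over = sel[sel > cap]
                if len(over):
                    rid = over.index.get_level_values("record_id")[0]
                    raise ValidationError(
                        f"record {rid}: {int(over.iloc[0])} {role} slots exceeds "
                        f"the {src} cap of {cap}"
                    )

        for src, (start, end) in self.coverage.items():
            if start.month_index > end.month_index:
                raise ValidationError(f"coverage for {src} has start after end")
        if self.coverage and len(self.events):
            em = month_idx_of(self.events["event_date"])
            for src, (start, end) in self.coverage.items():
                mask = (self.events["source"] == src).to_numpy()
                out = mask & ((em < start.month_index) | (em > end.month_index))
                if out.any():
                    rows = self.events.index[out][:5].tolist()
                    raise ValidationError(
                        f"{src} events outside coverage "
                        f"{start.isoformat()}..{end.isoformat()}: rows {rows}"
                    )
            uncovered = ~self.events["source"].isin(self.coverage)
            if uncovered.any():
                raise ValidationError(
                    "events from sources without a coverage window: "
                    f"{sorted(self.events.loc[uncovered, 'source'].unique())}"
                )
        return self


@dataclass
class ExclusionReport:
    """Per-person exclusion log from :func:`apply_exclusions`."""

    excluded: pd.DataFrame  # columns: person_id, reason
    n_before: int
    n_after: int

    def counts(self) -> dict[str, int]:
        return self.excluded["reason"].value_counts().to_dict()


def apply_exclusions(cohort: Cohort, min_age: float = 45.0) -> tuple[Cohort, ExclusionReport]:
    """Drop ineligible persons and all of their records.

    A person is excluded when younger than ``min_age`` at baseline, or when
    carrying irreconcilable linked data — operationalised as any event dated
    strictly after the death date (month-level comparison unless both dates
    carry a day).  Idempotent: a second application removes nobody.
    """
    persons = cohort.persons
    under = (persons["age_at_baseline"] < min_age).to_numpy()

    death_m = month_idx_of(persons["death_date"])
    death_d = day_of(persons["death_date"])
    dm = pd.Series(death_m, index=persons["person_id"].to_numpy())
    dd = pd.Series(death_d, index=persons["person_id"].to_numpy())

    ev = cohort.events
    after_death_ids: set[str] = set()
    if len(ev):
        em = month_idx_of(ev["event_date"])
        ed = day_of(ev["event_date"])
        pdm = dm.reindex(ev["person_id"]).to_numpy()
        pdd = dd.reindex(ev["person_id"]).to_numpy()
        with np.errstate(invalid="ignore"):
            later_month = em > pdm
            same_month_later_day = (
                (em == pdm) & ~np.isnan(ed) & ~np.isnan(pdd) & (ed > pdd)
            )
        bad = np.nan_to_num(later_month | same_month_later_day).astype(bool)
        after_death_ids = set(ev.loc[bad, "person_id"])

    rows = []
    for pid, is_under in zip(persons["person_id"], under):
        if is_under:
            rows.append((pid, "under_min_age"))
        elif pid in after_death_ids:
            rows.append((pid, "event_after_death"))
    report = ExclusionReport(
        excluded=pd.DataFrame(rows, columns=["person_id", "reason"]),
        n_before=len(persons),
        n_after=len(persons) - len(rows),
    )
    drop = set(report.excluded["person_id"])
    kept = replace(
        cohort,
        persons=persons[~persons["person_id"].isin(drop)].reset_index(drop=True),
        events=cohort.events[~cohort.events["person_id"].isin(drop)].reset_index(drop=True),
        registry=cohort.registry[~cohort.registry["person_id"].isin(drop)].reset_index(drop=True),
    )
    return kept, report
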