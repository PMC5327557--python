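"""Synthetic linked administrative cohorts with known ground truth.

The generator emulates the statistical structure of a state-wide linked
data asset: a recruited cohort of older adults, a gold-standard cancer
registry with month-precision diagnosis dates, and five surrogate sources
(hospital admissions, emergency presentations, medical and pharmaceutical
claims, death records) that observe true cases imperfectly:

* a true incident case is coded in hospital data with probability
  ``p_code``, at a month offset drawn from a lag distribution that
  includes one pre-diagnosis month and a tail beyond the matching window;
* border residents suffer interstate hospitalisation loss (a capture
  penalty multiplying ``p_code``), as do cases with unknown spread of
  disease (less health-system contact);
* prevalent cases — diagnosed before the study window — are re-coded in
  hospital during the window, contaminating the false-positive pool;
* random miscoding adds false primary-site codes at a small
  per-person-month rate;
* cancer deaths are certified with the primary site as cause with a
  coding probability, and a small share of non-case deaths are miscoded
  as primary cancer (some with a secondary-malignancy code elsewhere in
  their linked records).

All randomness flows through named substreams derived from one seed, so
identical configurations are byte-identical and adding a source never
perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import EVENT_COLUMNS, PERSON_COLUMNS, REGISTRY_COLUMNS, Cohort
from .dates import StudyDate
from .errors import ConfigurationError

_NEVER = 10**7  # month index standing in for "does not happen"


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class LagDistribution:
    """Distribution of (event month − diagnosis month) given detection."""

    probs: tuple[tuple[int, float], ...]

    def __post_init__(self):
        total = sum(p for _, p in self.probs)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"lag probabilities sum to {total}, not 1")
        for off, p in self.probs:
            _check_prob(p, f"lag P({off})")

    @property
    def offsets(self) -> np.ndarray:
        return np.array([o for o, _ in self.probs], dtype=int)

    @property
    def pvals(self) -> np.ndarray:
        return np.array([p for _, p in self.probs], dtype=float)

    @classmethod
    def from_dict(cls, d: dict) -> "LagDistribution":
        return cls(tuple(sorted((int(k), float(v)) for k, v in d.items())))


@dataclass(frozen=True)
class TreatmentModel:
    """Probabilities of treatment records given a (detected) case."""

    p_surgery: float = 0.0
    p_chemo: float = 0.0
    p_radio: float = 0.0
    p_claim_echo: float = 0.7   # inpatient procedure also billed as a claim item
    p_pbs_supply: float = 0.8   # chemotherapy drug supply recorded in pharmacy claims
    background_surgery: float = 0.0  # per-person prob of a look-alike procedure, non-cases
    background_chemo: float = 0.0
    background_radio: float = 0.0

    def __post_init__(self):
        for f_ in ("p_surgery", "p_chemo", "p_radio", "p_claim_echo", "p_pbs_supply",
                   "background_surgery", "background_chemo", "background_radio"):
            _check_prob(getattr(self, f_), f_)


@dataclass(frozen=True)
class CancerModel:
    """Generative parameters for one cancer type."""

    name: str
    codes: tuple[str, ...]                  # primary-site ICD-10 prefixes
    history_code: str                       # personal-history (Z85.x) code
    emission_codes: tuple[str, ...]         # concrete codes written into events
    secondary_code: str                     # C77–C79 code for metastases of other primaries
    monthly_incidence: float
    p_code: float                           # hospital coding probability per true case
    lag: LagDistribution
    unknown_spread_penalty: float = 1.0     # multiplier on p_code when spread unknown
    spread_dist: tuple[tuple[str, float], ...] = (
        ("localised", 0.40), ("regional", 0.30), ("distant", 0.12), ("unknown", 0.18),
    )
    prevalent_fraction: float = 0.0         # diagnosed before the window
    recode_probability: float = 0.0         # prevalent case re-coded during window
    miscode_monthly: float = 0.0            # false primary code, per person-month
    case_fatality_monthly: float = 0.0
    death_cause_coding: float = 0.9         # fatal case certified with primary site
    prevalent_death_cause_coding: float = 0.35
    noncase_death_cause_fp: float = 0.0     # non-case death miscoded as primary cancer
    secondary_code_fraction: float = 0.4    # of those, share with a C77–C79 record
    history_probability: float = 0.4        # detected case later coded Z85.x
    prevalent_history_probability: float = 0.6
    p_emergency: float = 0.0
    emergency_icd10_share: float = 0.7      # remainder coded SNOMED (unmapped)
    treatment: TreatmentModel = field(default_factory=TreatmentModel)
    surgery_achi: tuple[str, ...] = ()
    chemo_achi: tuple[str, ...] = ()
    radio_achi: tuple[str, ...] = ()
    surgery_mbs: tuple[str, ...] = ()
    chemo_mbs: tuple[str, ...] = ()
    radio_mbs: tuple[str, ...] = ()
    pbs_items: tuple[str, ...] = ()

    def __post_init__(self):
        for f_ in ("monthly_incidence", "p_code", "unknown_spread_penalty",
                   "prevalent_fraction", "recode_probability", "miscode_monthly",
                   "case_fatality_monthly", "death_cause_coding",
                   "prevalent_death_cause_coding", "noncase_death_cause_fp",
                   "secondary_code_fraction", "history_probability",
                   "prevalent_history_probability", "p_emergency",
                   "emergency_icd10_share"):
            _check_prob(getattr(self, f_), f"{self.name}.{f_}")
        total = sum(p for _, p in self.spread_dist)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"{self.name}: spread_dist sums to {total}")


@dataclass(frozen=True)
class Demographics:
    age_mean: float = 62.0
    age_sd: float = 11.0
    age_min: float = 45.0
    age_max: float = 99.0
    female_fraction: float = 0.53
    nonmetro_fraction: float = 0.40
    border_fraction: float = 0.08

    def __post_init__(self):
        for f_ in ("female_fraction", "nonmetro_fraction", "border_fraction"):
            _check_prob(getattr(self, f_), f_)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full generative configuration; defaults via :func:`default_config`."""

    n_persons: int = 50_000
    seed: int = 0
    study_start: StudyDate = StudyDate(2006, 2)   # evaluation window = registry overlap
    study_end: StudyDate = StudyDate(2010, 12)
    recruitment_start: StudyDate = StudyDate(2006, 1)
    recruitment_end: StudyDate = StudyDate(2009, 12)
    registry_history_start: StudyDate = StudyDate(1994, 1)
    inpatient_start: StudyDate = StudyDate(2001, 7)
    followup_end: StudyDate = StudyDate(2014, 6)  # hospital data extend past the registry
    emergency_start: StudyDate = StudyDate(2005, 1)
    emergency_end: StudyDate = StudyDate(2014, 12)
    claims_start: StudyDate = StudyDate(2004, 6)
    claims_end: StudyDate = StudyDate(2014, 12)
    death_start: StudyDate = StudyDate(2006, 1)
    death_end: StudyDate = StudyDate(2012, 12)
    border_capture_penalty: float = 0.5           # interstate hospitalisation loss
    background_mortality_monthly: float = 0.001
    demographics: Demographics = field(default_factory=Demographics)
    cancers: tuple[CancerModel, ...] = ()

    def validate(self) -> "SyntheticCohortConfig":
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        _check_prob(self.border_capture_penalty, "border_capture_penalty")
        _check_prob(self.background_mortality_monthly, "background_mortality_monthly")
        if self.study_start.month_index > self.study_end.month_index:
            raise ConfigurationError("study window start after end")
        if not self.cancers:
            raise ConfigurationError("at least one cancer type required")
        return self

    def coverage(self) -> dict[str, tuple[StudyDate, StudyDate]]:
        return {
            "inpatient": (self.inpatient_start, self.followup_end),
            "emergency": (self.emergency_start, self.emergency_end),
            "claims_medical": (self.claims_start, self.claims_end),
            "claims_pharma": (self.claims_start, self.claims_end),
            "death": (self.death_start, self.death_end),
        }

    @property
    def eval_window(self) -> tuple[StudyDate, StudyDate]:
        return (self.study_start, self.study_end)


def default_config(n_persons: int = 50_000, seed: int = 0) -> SyntheticCohortConfig:
    """Two-cancer configuration emulating a colorectal + lung validation study.

    Incidence, coding probabilities and lag shapes reflect a large 45+
    cohort followed for about five registry years: colorectal cancer is
    coded promptly and nearly always (high surgery rates), lung cancer
    less completely and with longer lags but with most fatal cases
    certified on death records.
    """
    colorectal = CancerModel(
        name="colorectal",
        codes=("C18", "C19", "C20"),
        history_code="Z85.0",
        emission_codes=("C18.0", "C18.2", "C18.7", "C18.9", "C19", "C20.9"),
        secondary_code="C78.5",
        monthly_incidence=1.45e-4,
        p_code=0.97,
        lag=LagDistribution.from_dict({-1: 0.03, 0: 0.87, 1: 0.04, 2: 0.02, 3: 0.02, 13: 0.02}),
        unknown_spread_penalty=0.75,
        prevalent_fraction=0.003,
        recode_probability=0.30,
        miscode_monthly=5e-6,
        case_fatality_monthly=0.012,
        noncase_death_cause_fp=0.002,
        p_emergency=0.04,
        treatment=TreatmentModel(
            p_surgery=0.85, p_chemo=0.45, p_radio=0.10,
            background_surgery=0.004, background_chemo=0.004, background_radio=0.004,
        ),
        surgery_achi=("32000", "32003", "32006"),
        chemo_achi=("96199",),
        radio_achi=("90764",),
        surgery_mbs=("32024", "32025"),
        chemo_mbs=("13950",),
        radio_mbs=("15275",),
        pbs_items=("FLUOROURACIL", "OXALIPLATIN"),
    )
    lung = CancerModel(
        name="lung",
        codes=("C34",),
        history_code="Z85.1",
        emission_codes=("C34.1", "C34.2", "C34.3", "C34.9"),
        secondary_code="C78.0",
        monthly_incidence=6.6e-5,
        p_code=0.88,
        lag=LagDistribution.from_dict(
            {-1: 0.03, 0: 0.55, 1: 0.10, 2: 0.08, 3: 0.06, 6: 0.07, 12: 0.05, 13: 0.06}
        ),
        unknown_spread_penalty=0.55,
        spread_dist=(("localised", 0.25), ("regional", 0.28), ("distant", 0.27), ("unknown", 0.20)),
        prevalent_fraction=0.0012,
        recode_probability=0.30,
        miscode_monthly=3e-6,
        case_fatality_monthly=0.040,
        noncase_death_cause_fp=0.004,
        p_emergency=0.06,
        treatment=TreatmentModel(
            p_surgery=0.20, p_chemo=0.50, p_radio=0.45,
            background_surgery=0.001, background_chemo=0.004, background_radio=0.004,
        ),
        surgery_achi=("38438", "38440"),
        chemo_achi=("96199",),
        radio_achi=("90764",),
        surgery_mbs=("38438",),
        chemo_mbs=("13950",),
        radio_mbs=("15275",),
        pbs_items=("CARBOPLATIN", "CISPLATIN", "DOCETAXEL"),
    )
    return SyntheticCohortConfig(n_persons=n_persons, seed=seed, cancers=(colorectal, lung))


@dataclass
class GroundTruth:
    """True labels behind a generated cohort.

    ``persons`` carries, per cancer type ``c``: ``case_{c}`` (incident in
    the extended follow-up), ``dx_month_{c}``, ``prevalent_{c}``,
    ``prevalent_dx_month_{c}``, ``detected_{c}`` and ``lag_{c}``; plus
    ``death_month`` and ``death_cause``.  ``event_mechanisms`` maps every
    emitted record to the single mechanism that produced it.
    """

    persons: pd.DataFrame
    event_mechanisms: pd.DataFrame  # record_id, person_id, cancer_type, mechanism


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


def _geometric0(rng: np.random.Generator, p: float, size: int) -> np.ndarray:
    """Months until an event under a constant monthly hazard (0, 1, 2, ...)."""
    if p <= 0:
        return np.full(size, _NEVER, dtype=np.int64)
    if p >= 1:
        return np.zeros(size, dtype=np.int64)
    return rng.geometric(p, size).astype(np.int64) - 1


def _iso(month_idx, day=None) -> str:
    d = StudyDate.from_month_index(int(month_idx))
    if day is None:
        return d.isoformat()
    return StudyDate(d.year, d.month, int(day)).isoformat()


class _EventLog:
    """Accumulates event records in deterministic construction order.

    Event days in a person's death month are clamped to the death day so a
    generated cohort never contains irreconcilable (post-mortem) records.
    """

    def __init__(self, death_lookup: dict | None = None) -> None:
        self.rows: list[tuple] = []
        self.mechanisms: list[tuple] = []
        self._rid = 0
        self._death = death_lookup or {}

    def add(self, pid: str, source: str, month: int, day: int | None,
            codes: list[tuple[str, str, str]], mechanism: str, cancer: str) -> None:
        rid = self._rid
        self._rid += 1
        dm = self._death.get(pid)
        if dm is not None and day is not None and month == dm[0]:
            day = min(int(day), dm[1])
        date = _iso(month, day)
        for slot, (role, system, code) in enumerate(codes):
            self.rows.append((rid, pid, source, date, role, system, code, slot))
        self.mechanisms.append((rid, pid, cancer, mechanism))

    def frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        events = pd.DataFrame(self.rows, columns=EVENT_COLUMNS)
        mech = pd.DataFrame(
            self.mechanisms,
            columns=["record_id", "person_id", "cancer_type", "mechanism"],
        )
        return events, mech


def generate_cohort(
    cfg: SyntheticCohortConfig, seed: int | None = None
) -> tuple[Cohort, GroundTruth]:
    """Generate a linked cohort and its ground truth.

    Reproducible: the same config and seed give byte-identical tables.
    Draw order is fixed — demographics first, then per cancer type (in
    config order) incidence, mortality, detection, contamination,
    miscoding, emergency, history, treatment — each on its own named
    substream, then death records.
    """
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    n = cfg.n_persons
    m0, m1 = cfg.study_start.month_index, cfg.study_end.month_index
    cov1 = cfg.followup_end.month_index
    M_ext = cov1 - m0 + 1
    hist0 = cfg.registry_history_start.month_index
    b0, b1 = cfg.recruitment_start.month_index, cfg.recruitment_end.month_index
    dem = cfg.demographics

    # --- demographics --------------------------------------------------
    rng = _rng(seed, "demographics")
    pids = np.array([f"P{i:07d}" for i in range(n)])
    age = np.round(np.clip(rng.normal(dem.age_mean, dem.age_sd, n), dem.age_min, dem.age_max))
    sex = np.where(rng.random(n) < dem.female_fraction, "female", "male")
    ses = rng.integers(1, 6, n)
    remoteness = np.where(
        rng.random(n) < dem.nonmetro_fraction, "non-metropolitan", "metropolitan"
    )
    border = rng.random(n) < dem.border_fraction
    base_m = b0 + rng.integers(0, b1 - b0 + 1, n)
    base_day = rng.integers(1, 29, n)

    truth = pd.DataFrame({"person_id": pids})
    log = _EventLog()
    registry_rows: list[tuple] = []

    death_m = np.full(n, _NEVER, dtype=np.int64)
    death_cause = np.array(["none"] * n, dtype=object)

    per_cancer: dict[str, dict[str, np.ndarray]] = {}

    # --- per-cancer truth and mortality (death resolved before events) --
    for cm in cfg.cancers:
        r_inc = _rng(seed, f"{cm.name}.incidence")
        q_ext = 1.0 - (1.0 - cm.monthly_incidence) ** M_ext
        case = r_inc.random(n) < q_ext
        dx = m0 + r_inc.integers(0, M_ext, n)
        spread_cats = [c for c, _ in cm.spread_dist]
        spread_p = [p for _, p in cm.spread_dist]
        spread = r_inc.choice(spread_cats, size=n, p=spread_p)
        prevalent = (~case) & (r_inc.random(n) < cm.prevalent_fraction)
        prev_dx = hist0 + r_inc.integers(0, max(1, m0 - hist0), n)
        prev_spread = r_inc.choice(spread_cats, size=n, p=spread_p)

        r_mort = _rng(seed, f"{cm.name}.mortality")
        T = _geometric0(r_mort, cm.case_fatality_monthly, n)
        cdeath = np.where(case, np.minimum(dx + T, _NEVER), _NEVER)
        earlier = cdeath < death_m
        death_m = np.where(earlier, cdeath, death_m)
        death_cause = np.where(earlier & (cdeath < _NEVER), cm.name, death_cause)

        per_cancer[cm.name] = {
            "case": case, "dx": dx, "T": T, "spread": spread,
            "prevalent": prevalent, "prev_dx": prev_dx, "prev_spread": prev_spread,
        }

    r_bg = _rng(seed, "mortality.background")
    Tb = _geometric0(r_bg, cfg.background_mortality_monthly, n)
    bdeath = base_m + Tb
    # cancer cases follow the case-fatality clock only; background mortality
    # applies to persons with no cancer (keeps survival-to-diagnosis coherent)
    any_case = np.zeros(n, dtype=bool)
    for st in per_cancer.values():
        any_case |= st["case"]
    no_cancer_death = (death_m >= _NEVER) & ~any_case
    use_bg = no_cancer_death & (bdeath < _NEVER)
    death_m = np.where(use_bg, bdeath, death_m)
    death_cause = np.where(use_bg, "other", death_cause)
    death_day = r_bg.integers(1, 29, n)

    # a recruited person was alive at baseline
    base_m = np.minimum(base_m, death_m)
    log._death = {
        pids[i]: (int(death_m[i]), int(death_day[i]))
        for i in np.flatnonzero(death_m < _NEVER)
    }

    truth["death_month"] = pd.array(
        np.where(death_m < _NEVER, death_m, pd.NA), dtype="Int64"
    )
    truth["death_cause"] = np.where(death_m < _NEVER, death_cause, None)

    # --- registry table -------------------------------------------------
    for cm in cfg.cancers:
        st = per_cancer[cm.name]
        case, dx, spread = st["case"], st["dx"], st["spread"]
        incident_in_registry = case & (dx <= m1)
        for i in np.flatnonzero(incident_in_registry):
            age_dx = round(age[i] + (dx[i] - base_m[i]) / 12.0, 1)
            registry_rows.append((pids[i], cm.name, _iso(dx[i]), spread[i], age_dx))
        for i in np.flatnonzero(st["prevalent"]):
            age_dx = round(age[i] + (st["prev_dx"][i] - base_m[i]) / 12.0, 1)
            registry_rows.append(
                (pids[i], cm.name, _iso(st["prev_dx"][i]), st["prev_spread"][i], age_dx)
            )

    # --- per-cancer surrogate events ------------------------------------
    for cm in cfg.cancers:
        st = per_cancer[cm.name]
        case, dx, T, spread = st["case"], st["dx"], st["T"], st["spread"]
        prevalent, prev_dx = st["prevalent"], st["prev_dx"]

        # hospital coding of true cases
        r_det = _rng(seed, f"{cm.name}.detection.inpatient")
        p_det = np.full(n, cm.p_code)
        p_det[border] *= cfg.border_capture_penalty
        p_det[spread == "unknown"] *= cm.unknown_spread_penalty
        detected = case & (r_det.random(n) < p_det)
        lag = r_det.choice(cm.lag.offsets, size=n, p=cm.lag.pvals)
        emit_code = r_det.choice(np.array(cm.emission_codes, dtype=object), size=n)
        day = r_det.integers(1, 29, n)
        ev_month = dx + lag
        emitted = detected & (lag <= T) & (ev_month <= death_m) & (ev_month <= cov1) & (
            ev_month >= cfg.inpatient_start.month_index
        )
        st["detected_emitted"] = emitted
        st["det_month"] = ev_month
        st["lag"] = lag
        for i in np.flatnonzero(emitted):
            log.add(pids[i], "inpatient", ev_month[i], day[i],
                    [("diagnosis", "ICD10", emit_code[i])], "true_case_coding", cm.name)

        # prevalent re-coding during the window
        r_cont = _rng(seed, f"{cm.name}.contamination")
        recode = prevalent & (r_cont.random(n) < cm.recode_probability)
        recode_m = m0 + r_cont.integers(0, m1 - m0 + 1, n)
        recode_code = r_cont.choice(np.array(cm.emission_codes, dtype=object), size=n)
        recode_day = r_cont.integers(1, 29, n)
        for i in np.flatnonzero(recode & (recode_m <= death_m)):
            log.add(pids[i], "inpatient", recode_m[i], recode_day[i],
                    [("diagnosis", "ICD10", recode_code[i])], "prevalent_recode", cm.name)

        # random miscoding over the whole hospital follow-up
        r_mis = _rng(seed, f"{cm.name}.miscode")
        alive_months = np.clip(np.minimum(death_m, cov1) - m0 + 1, 0, M_ext)
        k = r_mis.binomial(alive_months.astype(int), cm.miscode_monthly)
        for i in np.flatnonzero(k > 0):
            months = m0 + r_mis.choice(int(alive_months[i]), size=int(k[i]), replace=False)
            mday = r_mis.integers(1, 29, int(k[i]))
            mcode = r_mis.choice(np.array(cm.emission_codes, dtype=object), size=int(k[i]))
            for mth, dy, cd in zip(np.sort(months), mday, mcode):
                log.add(pids[i], "inpatient", mth, dy,
                        [("diagnosis", "ICD10", cd)], "miscode", cm.name)

        # emergency presentations (inconsistently coded)
        r_ed = _rng(seed, f"{cm.name}.emergency")
        ed = case & (r_ed.random(n) < cm.p_emergency)
        ed_m = dx + r_ed.integers(0, 2, n)
        ed_icd = r_ed.random(n) < cm.emergency_icd10_share
        ed_day = r_ed.integers(1, 29, n)
        ed_code = r_ed.choice(np.array(cm.emission_codes, dtype=object), size=n)
        e_lo, e_hi = cfg.emergency_start.month_index, cfg.emergency_end.month_index
        for i in np.flatnonzero(ed & (ed_m <= death_m) & (ed_m >= e_lo) & (ed_m <= e_hi)):
            if ed_icd[i]:
                codes = [("diagnosis", "ICD10", ed_code[i])]
            else:
                codes = [("diagnosis", "SNOMED", f"SCT{zlib.crc32(cm.name.encode()) % 10**6}")]
            log.add(pids[i], "emergency", ed_m[i], ed_day[i], codes, "ed_coding", cm.name)

        # history-of-cancer codes on later admissions
        r_hist = _rng(seed, f"{cm.name}.history")
        hist_flag = emitted & (r_hist.random(n) < cm.history_probability)
        hist_m = ev_month + r_hist.integers(2, 25, n)
        hist_day = r_hist.integers(1, 29, n)
        for i in np.flatnonzero(hist_flag & (hist_m <= np.minimum(death_m, cov1))):
            log.add(pids[i], "inpatient", hist_m[i], hist_day[i],
                    [("diagnosis", "ICD10", cm.history_code)], "history", cm.name)
        prev_hist = prevalent & (r_hist.random(n) < cm.prevalent_history_probability)
        ph_m = m0 + r_hist.integers(0, m1 - m0 + 1, n)
        ph_day = r_hist.integers(1, 29, n)
        for i in np.flatnonzero(prev_hist & (ph_m <= death_m)):
            log.add(pids[i], "inpatient", ph_m[i], ph_day[i],
                    [("diagnosis", "ICD10", cm.history_code)], "history_prevalent", cm.name)

        # treatment records
        tm = cm.treatment
        r_tr = _rng(seed, f"{cm.name}.treatment")
        c_lo, c_hi = cfg.claims_start.month_index, cfg.claims_end.month_index

        def _emit_treatment(flag, month, achi, mbs, mechanism, pbs=None):
            tday = r_tr.integers(1, 29, n)
            echo = r_tr.random(n) < tm.p_claim_echo
            supply = r_tr.random(n) < tm.p_pbs_supply
            achi_code = r_tr.choice(np.array(achi, dtype=object), size=n) if achi else None
            mbs_code = r_tr.choice(np.array(mbs, dtype=object), size=n) if mbs else None
            pbs_code = r_tr.choice(np.array(pbs, dtype=object), size=n) if pbs else None
            ok = flag & (month <= death_m) & (month <= cov1)
            for i in np.flatnonzero(ok):
                if achi_code is not None:
                    log.add(pids[i], "inpatient", month[i], tday[i],
                            [("procedure", "ACHI", achi_code[i])], mechanism, cm.name)
                if mbs_code is not None and echo[i] and c_lo <= month[i] <= c_hi:
                    log.add(pids[i], "claims_medical", month[i], tday[i],
                            [("item", "MBS_ITEM", mbs_code[i])], f"{mechanism}_claim", cm.name)
                if pbs_code is not None and supply[i] and c_lo <= month[i] <= c_hi:
                    log.add(pids[i], "claims_pharma", month[i], tday[i],
                            [("item", "PBS_ITEM", pbs_code[i])], f"{mechanism}_supply", cm.name)

        surgery = case & (r_tr.random(n) < tm.p_surgery)
        s_m = dx + r_tr.choice(np.array([0, 1, 2]), size=n, p=[0.7, 0.2, 0.1])
        _emit_treatment(surgery, s_m, cm.surgery_achi, cm.surgery_mbs, "surgery")
        chemo = case & (r_tr.random(n) < tm.p_chemo)
        ch_m = dx + r_tr.integers(1, 4, n)
        _emit_treatment(chemo, ch_m, cm.chemo_achi, cm.chemo_mbs, "chemo", cm.pbs_items)
        radio = case & (r_tr.random(n) < tm.p_radio)
        ra_m = dx + r_tr.integers(1, 4, n)
        _emit_treatment(radio, ra_m, cm.radio_achi, cm.radio_mbs, "radio")

        # look-alike treatment in non-cases (codes not exclusive to this cancer)
        for bg_p, achi, mbs, pbs, mech in (
            (tm.background_surgery, cm.surgery_achi, cm.surgery_mbs, None, "background_surgery"),
            (tm.background_chemo, cm.chemo_achi, cm.chemo_mbs, cm.pbs_items, "background_chemo"),
            (tm.background_radio, cm.radio_achi, cm.radio_mbs, None, "background_radio"),
        ):
            bg = (~case) & (r_tr.random(n) < bg_p)
            bg_m = m0 + r_tr.integers(0, m1 - m0 + 1, n)
            _emit_treatment(bg, bg_m, achi, mbs, mech, pbs)

        truth[f"case_{cm.name}"] = case
        truth[f"dx_month_{cm.name}"] = pd.array(np.where(case, dx, pd.NA), dtype="Int64")
        truth[f"prevalent_{cm.name}"] = prevalent
        truth[f"prevalent_dx_month_{cm.name}"] = pd.array(
            np.where(prevalent, prev_dx, pd.NA), dtype="Int64"
        )
        truth[f"detected_{cm.name}"] = emitted
        truth[f"lag_{cm.name}"] = pd.array(np.where(emitted, lag, pd.NA), dtype="Int64")
        truth[f"spread_{cm.name}"] = np.where(case, spread, None)

    # --- death records ---------------------------------------------------
    r_death = _rng(seed, "death_records")
    d_lo, d_hi = cfg.death_start.month_index, cfg.death_end.month_index
    other_causes = np.array(["I21.9", "I64", "J44.9", "E11.9", "I25.1"], dtype=object)
    u_cause = r_death.random(n)
    u_prev = {cm.name: r_death.random(n) for cm in cfg.cancers}
    u_fp = {cm.name: r_death.random(n) for cm in cfg.cancers}
    u_sec = {cm.name: r_death.random(n) for cm in cfg.cancers}
    other_pick = r_death.choice(other_causes, size=n)
    sec_m = m0 + r_death.integers(0, m1 - m0 + 1, n)
    sec_day = r_death.integers(1, 29, n)
    dead = (death_m >= d_lo) & (death_m <= d_hi)
    death_fp_mech = np.array([None] * n, dtype=object)
    for i in np.flatnonzero(dead):
        cause_code, mech, cancer = other_pick[i], "death_other", ""
        if death_cause[i] not in ("other", "none"):
            cm = next(c for c in cfg.cancers if c.name == death_cause[i])
            if u_cause[i] < cm.death_cause_coding:
                cause_code, mech, cancer = cm.emission_codes[-1], "death_cause", cm.name
        else:
            for cm in cfg.cancers:
                if per_cancer[cm.name]["prevalent"][i] and u_prev[cm.name][i] < cm.prevalent_death_cause_coding:
                    cause_code, mech, cancer = cm.emission_codes[-1], "death_cause_prevalent", cm.name
                    break
                if u_fp[cm.name][i] < cm.noncase_death_cause_fp and not per_cancer[cm.name]["case"][i]:
                    cause_code, mech, cancer = cm.emission_codes[-1], "death_cause_fp", cm.name
                    if u_sec[cm.name][i] < cm.secondary_code_fraction and sec_m[i] <= death_m[i]:
                        log.add(pids[i], "inpatient", sec_m[i], sec_day[i],
                                [("diagnosis", "ICD10", cm.secondary_code)],
                                "secondary_code", cm.name)
                        death_fp_mech[i] = "possible_secondary"
                    else:
                        death_fp_mech[i] = "other_disease"
                    break
        codes = [("cause_of_death", "ICD10", cause_code),
                 ("cause_of_death", "ICD10", "J18.9")]
        log.add(pids[i], "death", death_m[i], death_day[i], codes, mech, cancer)
    truth["death_fp_mechanism"] = death_fp_mech

    # --- assemble --------------------------------------------------------
    persons = pd.DataFrame(
        {
            "person_id": pids,
            "baseline_date": [
                _iso(m, min(d, 28)) for m, d in zip(base_m, base_day)
            ],
            "age_at_baseline": age,
            "sex": sex,
            "ses_quintile": ses,
            "remoteness": remoteness,
            "border_resident": border,
            # deaths are known only through the death-data linkage horizon
            "death_date": [
                _iso(m, d) if m <= d_hi else pd.NA for m, d in zip(death_m, death_day)
            ],
        },
        columns=PERSON_COLUMNS,
    )
    registry = pd.DataFrame(registry_rows, columns=REGISTRY_COLUMNS)
    events, mech = log.frames()
    cohort = Cohort(
        persons=persons, events=events, registry=registry, coverage=cfg.coverage()
    ).validate()
    return cohort, GroundTruth(persons=truth, event_mechanisms=mech)
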