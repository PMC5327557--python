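"""Run configuration: default indicator sets and YAML loading.

The default battery mirrors the indicator families available in linked
Australian administrative data: hospital diagnosis of the primary cancer,
personal-history (Z85.x) codes, surgical resection and chemo/radiotherapy
procedures, emergency-department diagnoses, medical and pharmaceutical
claim items, and cause-of-death records — plus the usual OR/AND
combination algorithms built on them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dates import StudyDate
from .errors import ConfigurationError
from .indicators import CompositeIndicator, IndicatorDefinition
from .synthetic import (
    CancerModel,
    Demographics,
    LagDistribution,
    SyntheticCohortConfig,
    TreatmentModel,
    default_config,
)


def default_indicators(
    cm: CancerModel,
) -> tuple[dict[str, IndicatorDefinition], list[CompositeIndicator]]:
    """Eleven individual indicators and six combination algorithms for one cancer."""
    p = cm.name

    def ind(suffix, **kw):
        return IndicatorDefinition(name=f"{p}_{suffix}", **kw)

    def maybe(suffix, codes, **kw):
        # cancer models without e.g. treatment codes simply lack that indicator
        if not codes:
            return None
        return ind(suffix, codes=codes, **kw)

    defs = {}
    for d in (
        ind("apdc_dx", source="inpatient", slot_role="diagnosis",
            code_system="ICD10", codes=cm.codes),
        maybe("apdc_history", (cm.history_code,) if cm.history_code else (),
              source="inpatient", slot_role="diagnosis", code_system="ICD10"),
        maybe("apdc_surgery", cm.surgery_achi, source="inpatient",
              slot_role="procedure", code_system="ACHI", prefix=False),
        maybe("apdc_chemo", cm.chemo_achi, source="inpatient",
              slot_role="procedure", code_system="ACHI", prefix=False),
        maybe("apdc_radio", cm.radio_achi, source="inpatient",
              slot_role="procedure", code_system="ACHI", prefix=False),
        ind("eddc_dx", source="emergency", slot_role="diagnosis",
            code_system="ICD10", codes=cm.codes),
        maybe("mbs_surgery", cm.surgery_mbs, source="claims_medical",
              slot_role="item", code_system="MBS_ITEM", prefix=False),
        maybe("mbs_chemo", cm.chemo_mbs, source="claims_medical",
              slot_role="item", code_system="MBS_ITEM", prefix=False),
        maybe("mbs_radio", cm.radio_mbs, source="claims_medical",
              slot_role="item", code_system="MBS_ITEM", prefix=False),
        maybe("pbs_chemo", cm.pbs_items, source="claims_pharma",
              slot_role="item", code_system="PBS_ITEM", prefix=False),
        ind("codurf_cause", source="death", slot_role="cause_of_death",
            code_system="ICD10", codes=cm.codes,
            cause_position="underlying_or_contributing"),
    ):
        if d is not None:
            defs[d.name] = d

    composites = [
        comp
        for comp in (
            CompositeIndicator(f"{p}_apdc_dx_or_history",
                               f"{p}_apdc_dx OR {p}_apdc_history"),
            CompositeIndicator(f"{p}_apdc_dx_or_surgery",
                               f"{p}_apdc_dx OR {p}_apdc_surgery"),
            CompositeIndicator(f"{p}_apdc_dx_and_surgery",
                               f"{p}_apdc_dx AND {p}_apdc_surgery",
                               anchor=f"{p}_apdc_dx"),
            CompositeIndicator(f"{p}_apdc_dx_or_eddc_dx",
                               f"{p}_apdc_dx OR {p}_eddc_dx"),
            CompositeIndicator(f"{p}_apdc_dx_and_codurf",
                               f"{p}_apdc_dx AND {p}_codurf_cause",
                               anchor=f"{p}_apdc_dx"),
            CompositeIndicator(f"{p}_apdc_dx_or_codurf",
                               f"{p}_apdc_dx OR {p}_codurf_cause"),
        )
        if all(leaf in defs for leaf in comp.leaves())
    ]
    return defs, composites


@dataclass
class RunConfig:
    """Everything a validation run needs.

    Exactly one of ``synthetic`` (generate a cohort) or ``input_dir``
    (read one from disk) must be set.  ``targets`` maps each cancer type
    to the indicator/composite names evaluated against it.
    """

    outdir: Path
    seed: int = 0
    synthetic: SyntheticCohortConfig | None = None
    input_dir: Path | None = None
    schema: dict | None = None
    eval_window: tuple[StudyDate, StudyDate] | None = None
    windows: tuple[int, ...] = (3, 12)
    indicators: dict[str, IndicatorDefinition] = field(default_factory=dict)
    composites: list[CompositeIndicator] = field(default_factory=list)
    targets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    ppv_floor: float = 0.8
    min_age: float = 45.0
    ci_method: str = "wilson"
    make_plots: bool = False

    def validate(self) -> "RunConfig":
        if (self.synthetic is None) == (self.input_dir is None):
            raise ConfigurationError("set exactly one of synthetic / input_dir")
        if not self.targets:
            raise ConfigurationError("at least one cancer type with indicators required")
        if any(w < 0 for w in self.windows) or not self.windows:
            raise ConfigurationError("windows must be non-empty, non-negative")
        if self.eval_window is None and self.synthetic is None:
            raise ConfigurationError("eval_window required when reading a cohort")
        names = set(self.indicators) | {c.name for c in self.composites}
        for cancer, targs in self.targets.items():
            missing = [t for t in targs if t not in names]
            if missing:
                raise ConfigurationError(f"{cancer}: unknown indicators {missing}")
        return self

    def resolved_eval_window(self) -> tuple[StudyDate, StudyDate]:
        if self.eval_window is not None:
            return self.eval_window
        return self.synthetic.eval_window

    def config_hash(self) -> str:
        payload = _to_jsonable(self)
        payload.pop("outdir", None)  # where results land is not configuration
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def default_run_config(
    outdir: str | Path, n_persons: int = 50_000, seed: int = 0, **kw
) -> RunConfig:
    """The full demonstration run: synthetic two-cancer cohort, 17 algorithms each."""
    syn = default_config(n_persons=n_persons, seed=seed)
    indicators: dict[str, IndicatorDefinition] = {}
    composites: list[CompositeIndicator] = []
    targets: dict[str, tuple[str, ...]] = {}
    for cm in syn.cancers:
        defs, comps = default_indicators(cm)
        indicators.update(defs)
        composites.extend(comps)
        targets[cm.name] = tuple(defs) + tuple(c.name for c in comps)
    return RunConfig(
        outdir=Path(outdir), seed=seed, synthetic=syn,
        indicators=indicators, composites=composites, targets=targets, **kw
    )


# --- serialisation -------------------------------------------------------

def _to_jsonable(obj):
    if isinstance(obj, StudyDate):
        return obj.isoformat()
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _lag_from_cfg(d) -> LagDistribution:
    return LagDistribution.from_dict(d)


def synthetic_config_from_dict(d: dict) -> SyntheticCohortConfig:
    """Build a generator configuration from a plain (YAML) mapping."""
    d = dict(d)
    cancers = []
    for c in d.pop("cancers", []):
        c = dict(c)
        c["lag"] = _lag_from_cfg(c["lag"])
        if "treatment" in c:
            c["treatment"] = TreatmentModel(**c["treatment"])
        if "spread_dist" in c:
            c["spread_dist"] = tuple((k, float(v)) for k, v in c["spread_dist"].items())
        for key in ("codes", "emission_codes", "surgery_achi", "chemo_achi",
                    "radio_achi", "surgery_mbs", "chemo_mbs", "radio_mbs", "pbs_items"):
            if key in c:
                c[key] = tuple(str(x) for x in c[key])
        cancers.append(CancerModel(**c))
    if "demographics" in d:
        d["demographics"] = Demographics(**d["demographics"])
    for key, val in list(d.items()):
        if key.endswith(("_start", "_end")) or key in ("study_start", "study_end"):
            d[key] = StudyDate.parse(val)
    return SyntheticCohortConfig(cancers=tuple(cancers), **d)


def _indicator_from_dict(d: dict) -> IndicatorDefinition:
    d = dict(d)
    for key in ("codes", "exact_codes"):
        if key in d:
            d[key] = tuple(str(x) for x in d[key])
    return IndicatorDefinition(**d)


def run_config_from_dict(d: dict, outdir: str | Path | None = None) -> RunConfig:
    d = dict(d)
    kw: dict = {}
    kw["outdir"] = Path(outdir or d.pop("outdir", "results"))
    d.pop("outdir", None)
    if "synthetic" in d:
        kw["synthetic"] = synthetic_config_from_dict(d.pop("synthetic"))
    if "input_dir" in d:
        kw["input_dir"] = Path(d.pop("input_dir"))
    if "eval_window" in d:
        lo, hi = d.pop("eval_window")
        kw["eval_window"] = (StudyDate.parse(lo), StudyDate.parse(hi))
    inds = {}
    for item in d.pop("indicators", []):
        ind = _indicator_from_dict(item)
        inds[ind.name] = ind
    comps = [CompositeIndicator(**c) for c in d.pop("composites", [])]
    kw["indicators"] = inds
    kw["composites"] = comps
    if "targets" in d:
        kw["targets"] = {k: tuple(v) for k, v in d.pop("targets").items()}
    if "windows" in d:
        kw["windows"] = tuple(int(w) for w in d.pop("windows"))
    for key in ("seed", "ppv_floor", "min_age", "ci_method", "make_plots", "schema"):
        if key in d:
            kw[key] = d.pop(key)
    if d:
        raise ConfigurationError(f"unknown run-config keys: {sorted(d)}")
    return RunConfig(**kw)


def load_run_config(path: str | Path, outdir: str | Path | None = None) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(yaml.safe_load(fh), outdir=outdir)
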