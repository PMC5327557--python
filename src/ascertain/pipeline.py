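"""End-to-end validation runs: cohort → indicators → classification → report.

``run_validation`` evaluates every configured indicator and combination
algorithm against the registry for every cancer type and matching window,
then flags the *optimal algorithm* per cancer type: the indicator with the
highest sensitivity among those whose PPV clears a configurable floor
(ties broken by higher PPV).  Reports are plain CSV/JSON and byte-stable
under a fixed seed — timestamps live only in the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .cohort import Cohort, apply_exclusions
from .config import RunConfig, _to_jsonable
from .dates import StudyDate
from .indicators import AscertainmentSet, evaluate_composite, extract_indicator
from .io import read_cohort
from .synthetic import generate_cohort
from .validation import (
    classify_cases,
    compute_metrics,
    count_incremental_cases,
    date_agnostic_ppv,
    lag_profile,
    stratify_mismatches,
    triage_death_fps,
)

log = logging.getLogger("ascertain")


@dataclass
class ReportBundle:
    """All artefacts of one validation run."""

    metrics: pd.DataFrame              # one row per indicator × cancer × window
    lag_profiles: pd.DataFrame
    optimal: dict                      # cancer type -> indicator name (or None)
    mismatch: dict                     # cancer type -> mismatch report (plain dict)
    triage: dict                       # cancer type -> discordance triage counts
    increments: dict                   # cancer type -> incremental-case report
    date_agnostic: dict                # cancer type -> date-agnostic PPV (of optimal)
    n_evaluated: int
    config_hash: str
    seed: int
    outputs: dict = field(default_factory=dict)  # artefact name -> path


def _load_cohort(rc: RunConfig) -> Cohort:
    if rc.synthetic is not None:
        cohort, _ = generate_cohort(rc.synthetic, seed=rc.seed)
        return cohort
    return read_cohort(rc.input_dir, rc.schema)


def _ascertain_all(
    rc: RunConfig, cohort: Cohort, eval_window: tuple[StudyDate, StudyDate]
) -> dict[str, AscertainmentSet]:
    sets: dict[str, AscertainmentSet] = {}
    for name, ind in rc.indicators.items():
        sets[name] = extract_indicator(
            cohort.events, ind, eval_window, coverage=cohort.coverage
        )
    for comp in rc.composites:
        sets[comp.name] = evaluate_composite(
            cohort.events, comp, rc.indicators, eval_window, coverage=cohort.coverage
        )
    return sets


def _pick_optimal(rows: list[dict], ppv_floor: float, window: int) -> str | None:
    """Lexicographic (sensitivity, PPV) subject to a PPV floor, at one window."""
    best, best_key = None, None
    for row in rows:
        if row["window_months"] != window:
            continue
        sens, ppv = row["sensitivity_pct"], row["ppv_pct"]
        if sens is None or ppv is None or ppv < 100 * ppv_floor:
            continue
        key = (sens, ppv)
        if best_key is None or key > best_key:
            best, best_key = row["indicator"], key
    return best


def run_validation(rc: RunConfig) -> ReportBundle:
    """Execute the full validation pipeline described by ``rc``."""
    rc.validate()
    outdir = Path(rc.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        return _run(rc, outdir)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(rc: RunConfig, outdir: Path) -> ReportBundle:
    cfg_hash = rc.config_hash()
    log.info("run start: config=%s seed=%d", cfg_hash, rc.seed)

    cohort = _load_cohort(rc)
    cohort, excl = apply_exclusions(cohort, min_age=rc.min_age)
    log.info("cohort: %d persons after %d exclusions", cohort.n_persons, len(excl.excluded))
    eval_window = rc.resolved_eval_window()
    n_eval = cohort.n_persons

    sets = _ascertain_all(rc, cohort, eval_window)

    metric_rows: list[dict] = []
    lag_rows: list[pd.DataFrame] = []
    classifications: dict[tuple[str, str, int], object] = {}
    for cancer, names in rc.targets.items():
        for name in names:
            for W in sorted(rc.windows):
                mc = classify_cases(sets[name], cohort.registry, cancer, eval_window, W)
                classifications[(cancer, name, W)] = mc
                metric_rows.append(compute_metrics(mc, n_eval, rc.ci_method).as_row())
            lp = lag_profile(classifications[(cancer, name, max(rc.windows))])
            t = lp.table.copy()
            t.insert(0, "indicator", name)
            t.insert(0, "cancer_type", cancer)
            t["negative_lag_fraction"] = lp.negative_lag_fraction
            lag_rows.append(t)
    metrics = pd.DataFrame(metric_rows)
    lags = pd.concat(lag_rows, ignore_index=True)

    optimal: dict[str, str | None] = {}
    mismatch: dict[str, dict] = {}
    triage: dict[str, dict] = {}
    increments: dict[str, dict] = {}
    agnostic: dict[str, float | None] = {}
    wmax = max(rc.windows)
    for cancer, names in rc.targets.items():
        rows = [r for r in metric_rows if r["cancer_type"] == cancer]
        best = _pick_optimal(rows, rc.ppv_floor, wmax)
        optimal[cancer] = best

        if best is not None:
            mc = classifications[(cancer, best, wmax)]
            rep = stratify_mismatches(mc, cohort.persons, cohort.registry)
            mismatch[cancer] = {
                "indicator": best,
                "groups": {g: _to_jsonable(s) for g, s in rep.groups.items()},
            }
            agnostic[cancer] = date_agnostic_ppv(sets[best], cohort.registry, cancer)

            # extend ascertainment past the registry's last month where the
            # surrogate source keeps running; combination algorithms mix
            # sources with different coverage ends, so the extension uses the
            # best single-source indicator instead
            best_simple = _pick_optimal(
                [r for r in rows if r["indicator"] in rc.indicators],
                rc.ppv_floor, wmax,
            )
            ind = rc.indicators.get(best_simple) if best_simple else None
            src_cov = cohort.coverage.get(ind.source) if ind else None
            if src_cov and src_cov[1].month_index > eval_window[1].month_index:
                ext = extract_indicator(
                    cohort.events, ind, (eval_window[0], src_cov[1]),
                    coverage=cohort.coverage,
                )
                inc = count_incremental_cases(
                    ext, cohort.registry, cancer, eval_window[1],
                    cohort.persons.set_index("person_id")["baseline_date"],
                )
                increments[cancer] = {"indicator": best_simple, **_to_jsonable(inc)}

        death_names = [
            nm for nm in names
            if rc.indicators.get(nm) is not None and rc.indicators[nm].source == "death"
        ]
        for nm in death_names:
            mc = classifications[(cancer, nm, wmax)]
            tri = triage_death_fps(mc, cohort.events, cohort.registry, cancer)
            triage[cancer] = {"indicator": nm, "counts": tri.counts, "total": tri.total}

    # --- write artefacts -------------------------------------------------
    outputs: dict[str, Path] = {}
    metrics_path = outdir / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    outputs["metrics"] = metrics_path
    lag_path = outdir / "lag_profiles.csv"
    lags.to_csv(lag_path, index=False)
    outputs["lag_profiles"] = lag_path
    for name, payload in (
        ("mismatch", mismatch), ("triage", triage),
        ("increments", increments), ("date_agnostic_ppv", agnostic),
        ("optimal", optimal),
    ):
        path = outdir / f"{name}.json"
        path.write_text(json.dumps(_to_jsonable(payload), indent=2, sort_keys=True))
        outputs[name] = path

    manifest = {
        "config_hash": cfg_hash,
        "seed": rc.seed,
        "n_evaluated": n_eval,
        "n_excluded": len(excl.excluded),
        "eval_window": [eval_window[0].isoformat(), eval_window[1].isoformat()],
        "windows": list(rc.windows),
        "tables": {k: str(v.name) for k, v in outputs.items()},
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = mpath

    if rc.make_plots:
        outputs["lag_plot"] = plot_lag_profiles(lags, outdir / "lag_profiles.png")

    log.info("run complete: %d metric rows", len(metrics))
    return ReportBundle(
        metrics=metrics,
        lag_profiles=lags,
        optimal=optimal,
        mismatch=mismatch,
        triage=triage,
        increments=increments,
        date_agnostic=agnostic,
        n_evaluated=n_eval,
        config_hash=cfg_hash,
        seed=rc.seed,
        outputs=outputs,
    )


def plot_lag_profiles(lags: pd.DataFrame, path: Path) -> Path:
    """Cumulative sensitivity/PPV after the registry diagnosis month."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cancers = sorted(lags["cancer_type"].unique())
    fig, axes = plt.subplots(1, len(cancers), figsize=(5 * len(cancers), 4), squeeze=False)
    for ax, cancer in zip(axes[0], cancers):
        sub = lags[lags["cancer_type"] == cancer]
        for name, grp in sub.groupby("indicator"):
            ax.plot(grp["offset_months"], 100 * grp["cum_sensitivity"], label=name, lw=1)
        ax.set_title(cancer)
        ax.set_xlabel("months after registry diagnosis")
        ax.set_ylabel("cumulative sensitivity (%)")
        ax.set_ylim(0, 100)
    axes[0][-1].legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
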