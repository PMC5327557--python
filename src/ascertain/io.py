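"""Delimited-text readers and writers for linked cohorts.

Tables are RFC-4180 CSV, UTF-8, with ISO-8601 dates (``YYYY-MM`` accepted
for month-precision fields).  A *schema* — a plain dict, typically loaded
from YAML — maps canonical column names onto the columns actually present
in each file and declares how code slots are laid out:

* ``long``: one row per code (columns ``slot_role``, ``code_system``,
  ``code``, optionally ``record_id`` and ``slot_index``);
* ``wide``: one row per record, with one column per code slot declared as
  ``code_groups`` (e.g. 55 diagnosis columns on an admissions extract).

The default schema below is what :mod:`ascertain.synthetic` writes, so a
generated cohort round-trips through ``write_cohort``/``read_cohort``
field-for-field.
"""

from __future__ import annotations

import copy
from pathlib import Path

import pandas as pd

from .cohort import (
    CODE_SYSTEMS,
    EVENT_COLUMNS,
    PERSON_COLUMNS,
    REGISTRY_COLUMNS,
    SOURCES,
    Cohort,
)
from .dates import StudyDate
from .errors import SchemaError, ValidationError


def _long_event_schema(source: str) -> dict:
    return {
        "file": f"events_{source}.csv",
        "source": source,
        "layout": "long",
        "columns": {c: c for c in EVENT_COLUMNS if c != "source"},
    }


DEFAULT_SCHEMA: dict = {
    "persons": {"file": "persons.csv", "columns": {c: c for c in PERSON_COLUMNS}},
    "registry": {"file": "registry.csv", "columns": {c: c for c in REGISTRY_COLUMNS}},
    "events": [_long_event_schema(s) for s in SOURCES],
    "coverage": {"file": "coverage.csv"},
}


def default_schema() -> dict:
    """A deep copy of the schema used by the synthetic generator's writer."""
    return copy.deepcopy(DEFAULT_SCHEMA)


def _require(df: pd.DataFrame, mapping: dict, needed: list[str], fname: str) -> None:
    missing = [mapping.get(c, c) for c in needed if mapping.get(c, c) not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: required columns missing: {missing}")


def _valid_date(value, allow_missing: bool) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NA:
        return allow_missing
    if isinstance(value, str) and value == "":
        return allow_missing
    try:
        StudyDate.parse(value)
        return True
    except ValidationError:
        return False


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype="string", keep_default_na=True)


def _wide_group_columns(group: dict) -> list[str]:
    if "columns" in group:
        return list(group["columns"])
    pattern, count = group["pattern"], int(group["count"])
    return [pattern.format(i) for i in range(1, count + 1)]


def read_cohort(directory: str | Path, schema: dict | None = None) -> Cohort:
    """Read a cohort from a directory of delimited-text tables.

    Rows failing type validation (unparseable dates, blank person ids) are
    rejected and logged in ``Cohort.diagnostics``; structural problems —
    missing columns, unknown code systems, events referencing unknown
    persons — raise :class:`SchemaError`, :class:`ValidationError` or
    :class:`ReferentialError` via :meth:`Cohort.validate`.
    """
    directory = Path(directory)
    schema = schema or default_schema()
    diagnostics: list[str] = []

    # --- persons -------------------------------------------------------
    pspec = schema["persons"]
    pfile = directory / pspec["file"]
    raw = _read_csv(pfile)
    pmap = pspec.get("columns", {})
    _require(raw, pmap, ["person_id", "baseline_date", "age_at_baseline"], pspec["file"])
    persons = pd.DataFrame()
    for canon in PERSON_COLUMNS:
        src = pmap.get(canon, canon)
        persons[canon] = raw[src] if src in raw.columns else pd.NA
    keep = pd.Series(True, index=persons.index)
    for i, row in persons.iterrows():
        if pd.isna(row["person_id"]) or row["person_id"] == "":
            diagnostics.append(f"{pspec['file']} row {i}: blank person_id; row rejected")
            keep[i] = False
        elif not _valid_date(row["baseline_date"], allow_missing=False):
            diagnostics.append(
                f"{pspec['file']} row {i}: bad baseline_date {row['baseline_date']!r}; row rejected"
            )
            keep[i] = False
        elif not _valid_date(row["death_date"], allow_missing=True):
            diagnostics.append(
                f"{pspec['file']} row {i}: bad death_date {row['death_date']!r}; row rejected"
            )
            keep[i] = False
    persons = persons[keep].reset_index(drop=True)
    persons["age_at_baseline"] = pd.to_numeric(persons["age_at_baseline"], errors="coerce")
    persons["ses_quintile"] = pd.to_numeric(persons["ses_quintile"], errors="coerce").astype("Int64")
    persons["border_resident"] = (
        persons["border_resident"].astype("string").str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        ).fillna(False).astype(bool)
    )
    persons["death_date"] = persons["death_date"].replace("", pd.NA)

    # --- registry ------------------------------------------------------
    rspec = schema["registry"]
    raw = _read_csv(directory / rspec["file"])
    rmap = rspec.get("columns", {})
    _require(raw, rmap, ["person_id", "cancer_type", "diagnosis_date"], rspec["file"])
    registry = pd.DataFrame()
    for canon in REGISTRY_COLUMNS:
        src = rmap.get(canon, canon)
        registry[canon] = raw[src] if src in raw.columns else pd.NA
    keep = pd.Series(True, index=registry.index)
    for i, row in registry.iterrows():
        if not _valid_date(row["diagnosis_date"], allow_missing=False):
            diagnostics.append(
                f"{rspec['file']} row {i}: bad diagnosis_date {row['diagnosis_date']!r}; row rejected"
            )
            keep[i] = False
    registry = registry[keep].reset_index(drop=True)
    registry["age_at_diagnosis"] = pd.to_numeric(registry["age_at_diagnosis"], errors="coerce")

    # --- events --------------------------------------------------------
    frames = []
    rid_offset = 0
    for espec in schema.get("events", []):
        path = directory / espec["file"]
        if not path.exists():
            continue
        raw = _read_csv(path)
        emap = espec.get("columns", {})
        layout = espec.get("layout", "long")
        source = espec["source"]
        if source not in SOURCES:
            raise SchemaError(f"{espec['file']}: unknown source {source!r}")
        _require(raw, emap, ["person_id", "event_date"], espec["file"])

        pid = raw[emap.get("person_id", "person_id")]
        date = raw[emap.get("event_date", "event_date")]
        ok = pd.Series(True, index=raw.index)
        for i in raw.index:
            if pd.isna(pid[i]) or pid[i] == "":
                diagnostics.append(f"{espec['file']} row {i}: blank person_id; row rejected")
                ok[i] = False
            elif not _valid_date(date[i], allow_missing=False):
                diagnostics.append(
                    f"{espec['file']} row {i}: bad event_date {date[i]!r}; row rejected"
                )
                ok[i] = False

        if layout == "long":
            _require(raw, emap, ["slot_role", "code_system", "code"], espec["file"])
            rid_col = emap.get("record_id", "record_id")
            slot_col = emap.get("slot_index", "slot_index")
            df = pd.DataFrame(
                {
                    "record_id": (
                        pd.to_numeric(raw[rid_col], errors="coerce")
                        if rid_col in raw.columns
                        else pd.Series(raw.index, index=raw.index)
                    ),
                    "person_id": pid,
                    "source": source,
                    "event_date": date,
                    "slot_role": raw[emap.get("slot_role", "slot_role")],
                    "code_system": raw[emap.get("code_system", "code_system")],
                    "code": raw[emap.get("code", "code")],
                    "slot_index": (
                        pd.to_numeric(raw[slot_col], errors="coerce")
                        if slot_col in raw.columns
                        else 0
                    ),
                }
            )[ok]
        elif layout == "wide":
            groups = espec.get("code_groups", [])
            if not groups:
                raise SchemaError(f"{espec['file']}: wide layout requires code_groups")
            rows = []
            for i in raw.index[ok]:
                slot = 0
                for g in groups:
                    system = g["code_system"]
                    if system not in CODE_SYSTEMS:
                        raise ValidationError(
                            f"{espec['file']}: unknown code_system {system!r}"
                        )
                    for col in _wide_group_columns(g):
                        if col not in raw.columns:
                            continue
                        code = raw.at[i, col]
                        if pd.isna(code) or code == "":
                            continue
                        rows.append(
                            (i, pid[i], source, date[i], g["slot_role"], system,
                             str(code), slot)
                        )
                        slot += 1
            df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        else:
            raise SchemaError(f"{espec['file']}: unknown layout {layout!r}")
        if len(df):
            df["record_id"] = df["record_id"].astype("int64") + rid_offset
            rid_offset = int(df["record_id"].max()) + 1
        frames.append(df)

    if frames:
        events = pd.concat(frames, ignore_index=True)
        events["slot_index"] = events["slot_index"].fillna(0).astype("int64")
        for c in ("person_id", "source", "event_date", "slot_role", "code_system", "code"):
            events[c] = events[c].astype(object)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)

    # --- coverage ------------------------------------------------------
    coverage: dict[str, tuple[StudyDate, StudyDate]] = {}
    cspec = schema.get("coverage")
    if cspec:
        cpath = directory / cspec["file"]
        if cpath.exists():
            cov = pd.read_csv(cpath, dtype="string")
            _require(cov, {}, ["source", "start", "end"], cspec["file"])
            for _, row in cov.iterrows():
                coverage[row["source"]] = (
                    StudyDate.parse(row["start"]),
                    StudyDate.parse(row["end"]),
                )

    for df in (persons, registry):
        for c in df.columns:
            if df[c].dtype == "string":
                df[c] = df[c].astype(object)
    cohort = Cohort(
        persons=persons, events=events, registry=registry,
        coverage=coverage, diagnostics=diagnostics,
    )
    return cohort.validate()


def write_cohort(cohort: Cohort, directory: str | Path, schema: dict | None = None) -> dict:
    """Write a cohort as CSV tables; returns ``{table: path}``.

    Events are written long, one file per source, using the schema's file
    names and canonical column names.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schema = schema or default_schema()
    paths = {}

    p = cohort.persons.copy()
    p["border_resident"] = p["border_resident"].map({True: "true", False: "false"})
    ppath = directory / schema["persons"]["file"]
    p.to_csv(ppath, index=False)
    paths["persons"] = ppath

    rpath = directory / schema["registry"]["file"]
    cohort.registry.to_csv(rpath, index=False)
    paths["registry"] = rpath

    cols = [c for c in EVENT_COLUMNS if c != "source"]
    for espec in schema.get("events", []):
        if espec.get("layout", "long") != "long":
            continue
        src = espec["source"]
        sub = cohort.events[cohort.events["source"] == src]
        epath = directory / espec["file"]
        sub[cols].to_csv(epath, index=False)
        paths[f"events_{src}"] = epath

    cspec = schema.get("coverage")
    if cspec:
        cov = pd.DataFrame(
            [
                (src, start.isoformat(), end.isoformat())
                for src, (start, end) in sorted(cohort.coverage.items())
            ],
            columns=["source", "start", "end"],
        )
        cpath = directory / cspec["file"]
        cov.to_csv(cpath, index=False)
        paths["coverage"] = cpath
    return paths
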