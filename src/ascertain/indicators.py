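"""Code-list indicators over event streams and their boolean algebra.

An :class:`IndicatorDefinition` is a declarative rule — "person has at
least one inpatient admission with an ICD-10 diagnosis code in C18–C20" —
evaluated over the events table to yield an :class:`AscertainmentSet`:
the set of flagged persons, each with the date of the *first* qualifying
event (admission date for hospital episodes, service/supply date for
claims, date of death for death records).

Codes match either exactly or by prefix: the three-character ICD-10
category ``C18`` covers ``C18.0``–``C18.9``.  Matching is dot- and
case-insensitive (``C18.2`` ≡ ``C182``).  Secondary-malignancy codes
(C77–C79) never appear in a primary-site code list, so metastases do not
trigger a primary-cancer indicator.

Indicators combine with OR (union, earliest date) and AND (intersection,
dated by a designated *anchor* component — for "hospital diagnosis AND
surgery" the diagnosis admission is the clinically meaningful date).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CODE_SYSTEMS, SLOT_ROLES, SOURCES, day_of, month_idx_of
from .dates import StudyDate
from .errors import ConfigurationError

__all__ = [
    "IndicatorDefinition", "CompositeIndicator", "AscertainmentSet",
    "extract_indicator", "combine_or", "combine_and", "evaluate_composite",
    "normalize_code", "parse_expression",
]


def normalize_code(code: str) -> str:
    """Canonical form used for matching: uppercase, no dots or spaces."""
    return str(code).upper().replace(".", "").replace(" ", "")


@dataclass(frozen=True)
class IndicatorDefinition:
    """A single code-list rule over one surrogate source.

    ``codes`` are treated as prefixes when ``prefix`` is True (the default,
    matching ICD-10 category semantics); ``exact_codes`` always match
    exactly.  For the death source, ``cause_position`` restricts matching
    to the underlying cause (slot 0) or allows any contributing cause.
    """

    name: str
    source: str
    slot_role: str
    code_system: str
    codes: tuple[str, ...] = ()
    prefix: bool = True
    exact_codes: tuple[str, ...] = ()
    cause_position: str = "underlying_or_contributing"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ConfigurationError(f"{self.name}: unknown source {self.source!r}")
        if self.slot_role not in SLOT_ROLES:
            raise ConfigurationError(f"{self.name}: unknown slot_role {self.slot_role!r}")
        if self.code_system not in CODE_SYSTEMS:
            raise ConfigurationError(f"{self.name}: unknown code_system {self.code_system!r}")
        if not (self.codes or self.exact_codes):
            raise ConfigurationError(f"{self.name}: empty code set")
        if self.cause_position not in ("underlying_or_contributing", "underlying_only"):
            raise ConfigurationError(
                f"{self.name}: bad cause_position {self.cause_position!r}"
            )
        for c in self.codes + self.exact_codes:
            if not re.fullmatch(r"[A-Z0-9.\- ]+", str(c).upper()):
                raise ConfigurationError(f"{self.name}: malformed code {c!r}")

    def matches(self, codes: pd.Series) -> np.ndarray:
        """Boolean mask of codes matching this rule (vectorised)."""
        norm = codes.astype("string").map(normalize_code, na_action="ignore")
        mask = np.zeros(len(codes), dtype=bool)
        exact = {normalize_code(c) for c in self.exact_codes}
        if not self.prefix:
            exact |= {normalize_code(c) for c in self.codes}
        if exact:
            mask |= norm.isin(exact).to_numpy()
        if self.prefix:
            for p in self.codes:
                mask |= norm.str.startswith(normalize_code(p)).fillna(False).to_numpy()
        return mask


@dataclass(frozen=True)
class CompositeIndicator:
    """A boolean expression over named indicators, e.g. ``"apdc_dx OR codurf_cause"``.

    AND binds tighter than OR; parentheses group.  ``anchor`` names the leaf
    whose first-occurrence date dates every AND node on its path (defaults
    to the expression's first leaf).
    """

    name: str
    expression: str
    anchor: str | None = None

    def leaves(self) -> tuple[str, ...]:
        return tuple(_tree_leaves(parse_expression(self.expression)))


@dataclass
class AscertainmentSet:
    """Persons flagged by an indicator, with first qualifying dates."""

    name: str
    cases: dict[str, StudyDate] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cases)

    def __contains__(self, person_id: str) -> bool:
        return person_id in self.cases

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.cases.items())
        return pd.DataFrame(
            {
                "person_id": [p for p, _ in items],
                "first_date": [d.isoformat() for _, d in items],
                "indicator": self.name,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str | None = None) -> "AscertainmentSet":
        nm = name or (df["indicator"].iloc[0] if len(df) else "ascertainment")
        return cls(nm, {r.person_id: StudyDate.parse(r.first_date) for r in df.itertuples()})


def _window_months(eval_window: tuple[StudyDate, StudyDate]) -> tuple[int, int]:
    start, end = eval_window
    if start.month_index > end.month_index:
        raise ConfigurationError("evaluation window start is after its end")
    return start.month_index, end.month_index


def extract_indicator(
    events: pd.DataFrame,
    ind: IndicatorDefinition,
    eval_window: tuple[StudyDate, StudyDate],
    coverage: dict | None = None,
    code_map: dict | None = None,
) -> AscertainmentSet:
    """Ascertain persons matching one code-list rule within a window.

    ``code_map`` optionally translates codes recorded in *other* coding
    systems into ``ind.code_system`` (``{(system, code): translated_code}``);
    without it, only same-system codes can match (emergency data mix ICD-9,
    ICD-10 and SNOMED).  First dates tie-break within a month by day
    present first, then day, then record order.
    """
    lo, hi = _window_months(eval_window)
    if coverage and ind.source in coverage:
        cs, ce = coverage[ind.source]
        if lo < cs.month_index or hi > ce.month_index:
            raise ConfigurationError(
                f"evaluation window {eval_window[0]}..{eval_window[1]} outside "
                f"{ind.source} coverage {cs}..{ce}"
            )

    sub = events[
        (events["source"] == ind.source) & (events["slot_role"] == ind.slot_role)
    ]
    if ind.source == "death" and ind.cause_position == "underlying_only":
        sub = sub[sub["slot_index"] == 0]
    if len(sub) == 0:
        return AscertainmentSet(ind.name, {})

    codes = sub["code"].copy()
    same = (sub["code_system"] == ind.code_system).to_numpy()
    if code_map:
        translated = [
            code_map.get((s, normalize_code(c)))
            for s, c in zip(sub["code_system"], sub["code"])
        ]
        has_tr = np.array([t is not None for t in translated])
        codes = codes.where(~(has_tr & ~same), pd.Series(translated, index=sub.index))
        same = same | has_tr
    matched = ind.matches(codes) & same
    sub = sub[matched]
    if len(sub) == 0:
        return AscertainmentSet(ind.name, {})

    m = month_idx_of(sub["event_date"])
    in_win = (m >= lo) & (m <= hi)
    sub = sub[in_win]
    if len(sub) == 0:
        return AscertainmentSet(ind.name, {})

    d = day_of(sub["event_date"])
    order = pd.DataFrame(
        {
            "person_id": sub["person_id"].to_numpy(),
            "event_date": sub["event_date"].to_numpy(),
            "m": m[in_win],
            "absent_day": np.isnan(d).astype(int),
            "day": np.nan_to_num(d),
            "record_id": sub["record_id"].to_numpy(),
            "slot_index": sub["slot_index"].to_numpy(),
        }
    )
    order = order.sort_values(
        ["person_id", "m", "absent_day", "day", "record_id", "slot_index"],
        kind="mergesort",
    ).drop_duplicates("person_id", keep="first")
    return AscertainmentSet(
        ind.name,
        {r.person_id: StudyDate.parse(r.event_date) for r in order.itertuples()},
    )


def combine_or(sets: list[AscertainmentSet], name: str | None = None) -> AscertainmentSet:
    """Union of ascertainment sets; first date is the earliest across inputs.

    Intra-month ties (equal sort keys) resolve in favour of the earlier
    input set.
    """
    out: dict[str, StudyDate] = {}
    for s in sets:
        for pid, d in s.cases.items():
            if pid not in out or d.sort_key() < out[pid].sort_key():
                out[pid] = d
    return AscertainmentSet(name or " OR ".join(s.name for s in sets), out)


def combine_and(
    sets: list[AscertainmentSet], anchor: str, name: str | None = None
) -> AscertainmentSet:
    """Intersection of ascertainment sets, dated by the ``anchor`` set."""
    by_name = {s.name: s for s in sets}
    if anchor not in by_name:
        raise ConfigurationError(
            f"anchor {anchor!r} not among combined sets {sorted(by_name)}"
        )
    common = set(sets[0].cases)
    for s in sets[1:]:
        common &= set(s.cases)
    anchor_set = by_name[anchor]
    return AscertainmentSet(
        name or " AND ".join(s.name for s in sets),
        {pid: anchor_set.cases[pid] for pid in common},
    )


# --- expression parsing -------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|\bOR\b|\bAND\b|[A-Za-z_][A-Za-z0-9_]*", re.IGNORECASE)


def parse_expression(expr: str):
    """Parse ``"a AND (b OR c)"`` into a nested tuple tree.

    Returns ``("leaf", name)``, ``("and", [subtrees])`` or
    ``("or", [subtrees])``; AND binds tighter than OR.
    """
    tokens = _TOKEN_RE.findall(expr)
    if "".join(tokens).replace(" ", "") != re.sub(r"\s+", "", expr):
        raise ConfigurationError(f"unparseable expression {expr!r}")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() is not None and peek().upper() == "OR":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and():
        factors = [parse_atom()]
        while peek() is not None and peek().upper() == "AND":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_atom():
        tok = peek()
        if tok is None:
            raise ConfigurationError(f"unexpected end of expression in {expr!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ConfigurationError(f"unbalanced parentheses in {expr!r}")
            take()
            return node
        if tok == ")" or tok.upper() in ("AND", "OR"):
            raise ConfigurationError(f"unexpected token {tok!r} in {expr!r}")
        return ("leaf", take())

    tree = parse_or()
    if pos != len(tokens):
        raise ConfigurationError(f"trailing tokens in {expr!r}")
    return tree


def _tree_leaves(tree) -> list[str]:
    kind = tree[0]
    if kind == "leaf":
        return [tree[1]]
    out = []
    for sub in tree[1]:
        out.extend(_tree_leaves(sub))
    return out


def evaluate_composite(
    events: pd.DataFrame,
    comp: CompositeIndicator,
    definitions: dict[str, IndicatorDefinition],
    eval_window: tuple[StudyDate, StudyDate],
    coverage: dict | None = None,
    code_map: dict | None = None,
) -> AscertainmentSet:
    """Evaluate a boolean indicator expression over the events table.

    Leaves are extracted with :func:`extract_indicator`; OR nodes take the
    earliest date; AND nodes are dated by the branch containing the
    composite's anchor leaf (the first leaf when no anchor is declared).
    """
    tree = parse_expression(comp.expression)
    leaves = _tree_leaves(tree)
    unknown = [n for n in leaves if n not in definitions]
    if unknown:
        raise ConfigurationError(f"{comp.name}: undefined indicators {unknown}")
    anchor = comp.anchor or leaves[0]
    if anchor not in leaves:
        raise ConfigurationError(f"{comp.name}: anchor {anchor!r} is not a leaf")

    cache: dict[str, AscertainmentSet] = {}

    def extract(nm: str) -> AscertainmentSet:
        if nm not in cache:
            cache[nm] = extract_indicator(
                events, definitions[nm], eval_window, coverage, code_map
            )
        return cache[nm]

    def evaluate(node) -> tuple[AscertainmentSet, bool]:
        # returns (set, contains_anchor)
        kind = node[0]
        if kind == "leaf":
            return extract(node[1]), node[1] == anchor
        results = [evaluate(sub) for sub in node[1]]
        sets = [s for s, _ in results]
        has_anchor = any(h for _, h in results)
        if kind == "or":
            return combine_or(sets), has_anchor
        date_source = next((s for s, h in results if h), sets[0])
        # give children unique names so combine_and can address the anchor branch
        named = [
            AscertainmentSet(f"__{i}", s.cases) for i, s in enumerate(sets)
        ]
        idx = sets.index(date_source)
        combined = combine_and(named, anchor=f"__{idx}")
        return AscertainmentSet(combined.name, combined.cases), has_anchor

    result, _ = evaluate(tree)
    return AscertainmentSet(comp.name, result.cases)
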