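"""Domain model for scenario-chart encoded medical interview records.

A medical interview narrative is formalised as an *object model*: three
entities (the doctor, the patient, and the patient's record) exchange typed
events, and ordered sequences of those events are grouped into *charts* — a
linear subset of Live Sequence Charts, one chart per narrative category
(personal background, diseases, surgeries, treatments, ...).  A shared,
dynamically growing *vocabulary* declares every event name once, with a fixed
parameter signature, so that records from many patients stay mutually
comparable and machine-checkable.

Conventions carried throughout the package:

* event names are case-sensitive identifiers (``[A-Za-z][A-Za-z0-9_]*``);
  free text such as ``"Shoulder Dislocation"`` lives in TEXT arguments;
* a duration of ``-1`` weeks is the *ongoing* sentinel — the patient never
  recovered from the condition;
* the first body event of a chart is its activation event; ``activates``
  links let progress in one chart switch further charts on.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import networkx as nx
import pandas as pd

IDENTIFIER_RE = re.compile(r"[A-Za-z][A-Za-z0-9_]*\Z")
ENTITY_ID_RE = re.compile(r"[A-Za-z0-9_.-]+\Z")


class ArityConflict(Exception):
    """An event name is being redeclared with a different signature."""


class _Wildcard:
    """Singleton placeholder for 'any value' in query patterns."""

    _instance: Optional["_Wildcard"] = None

    def __new__(cls) -> "_Wildcard":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "*"


#: Matches any argument value in a query pattern; never valid inside a record.
WILDCARD = _Wildcard()


class Role(str, enum.Enum):
    """The three participating entities of every interview scenario."""

    DOCTOR = "DOCTOR"
    PATIENT = "PATIENT"
    RECORD = "RECORD"


@dataclass(frozen=True)
class EntityRef:
    """A reference to one concrete entity, e.g. ``PATIENT:patientX``."""

    role: Role
    id: str

    def __post_init__(self) -> None:
        if not isinstance(self.role, Role):
            object.__setattr__(self, "role", Role(self.role))
        if not ENTITY_ID_RE.match(self.id):
            raise ValueError(f"invalid entity id {self.id!r}")

    def render(self) -> str:
        return f"{self.role.value}:{self.id}"

    @classmethod
    def parse(cls, text: str) -> "EntityRef":
        role, sep, eid = text.partition(":")
        if not sep:
            raise ValueError(f"entity reference {text!r} lacks ROLE:id form")
        return cls(Role(role), eid)


class PType(str, enum.Enum):
    """Parameter types of the event vocabulary."""

    TEXT = "TEXT"
    INT = "INT"
    YEAR = "YEAR"
    AGE_YEARS = "AGE_YEARS"
    DURATION_WEEKS = "DURATION_WEEKS"


def check_value(ptype: PType, value: object) -> Optional[str]:
    """Return an error message if *value* violates *ptype*, else None.

    YEAR is a 4-digit year in [1900, 2100]; AGE_YEARS lies in [0, 130];
    DURATION_WEEKS is nonnegative or exactly -1 (the ongoing sentinel).
    """
    if ptype is PType.TEXT:
        return None if isinstance(value, str) else f"expected text, got {value!r}"
    if not isinstance(value, int) or isinstance(value, bool):
        return f"expected integer, got {value!r}"
    if ptype is PType.YEAR and not 1900 <= value <= 2100:
        return f"YEAR {value} outside [1900, 2100]"
    if ptype is PType.AGE_YEARS and not 0 <= value <= 130:
        return f"AGE_YEARS {value} outside [0, 130]"
    if ptype is PType.DURATION_WEEKS and value < -1:
        return f"DURATION_WEEKS {value} must be >= 0 or the ongoing sentinel -1"
    return None


@dataclass(frozen=True)
class ParamSpec:
    name: str
    ptype: PType

    def __post_init__(self) -> None:
        if not isinstance(self.ptype, PType):
            object.__setattr__(self, "ptype", PType(self.ptype))


class EventKind(str, enum.Enum):
    """GENERIC events describe a parameterised class of occurrences (a
    fatigue-state change, a surgery); SPECIFIC events name one concrete item
    (a particular medicine)."""

    GENERIC = "GENERIC"
    SPECIFIC = "SPECIFIC"


class Tag(str, enum.Enum):
    """Coarse semantic tag on a vocabulary entry, used for exports."""

    MEDICINE = "MEDICINE"
    SYMPTOM = "SYMPTOM"
    PROCEDURE = "PROCEDURE"
    ADMIN = "ADMIN"
    OTHER = "OTHER"


@dataclass(frozen=True)
class EventDecl:
    """One vocabulary entry: a named event with a fixed parameter signature."""

    name: str
    kind: EventKind
    params: tuple[ParamSpec, ...] = ()
    tag: Optional[Tag] = None

    def __post_init__(self) -> None:
        if not isinstance(self.kind, EventKind):
            object.__setattr__(self, "kind", EventKind(self.kind))
        if self.tag is not None and not isinstance(self.tag, Tag):
            object.__setattr__(self, "tag", Tag(self.tag))
        object.__setattr__(self, "params", tuple(self.params))
        if not IDENTIFIER_RE.match(self.name):
            raise ValueError(f"event name {self.name!r} is not an identifier")
        if self.kind is EventKind.GENERIC and not self.params:
            raise ValueError(f"GENERIC event {self.name!r} needs >= 1 parameter")

    @property
    def arity(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class EventInstance:
    """One occurrence of a declared event between two entities.

    ``args`` must match the declared signature; in query patterns an argument
    may be :data:`WILDCARD`.
    """

    name: str
    source: EntityRef
    target: EntityRef
    args: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "args", tuple(self.args))


class Category(str, enum.Enum):
    """Narrative category of a chart; OTHER takes a free subcategory label."""

    INQUIRY = "INQUIRY"
    PERSONAL_BACKGROUND = "PERSONAL_BACKGROUND"
    PSYCHIATRY_BACKGROUND = "PSYCHIATRY_BACKGROUND"
    MEDICAL_BACKGROUND = "MEDICAL_BACKGROUND"
    DISEASES = "DISEASES"
    INJURIES = "INJURIES"
    SURGERIES = "SURGERIES"
    ABNORMAL_RESPONSE = "ABNORMAL_RESPONSE"
    FATIGUE_BACKGROUND = "FATIGUE_BACKGROUND"
    DEVELOPMENT = "DEVELOPMENT"
    TREATMENT_PAST_INEFFECTIVE = "TREATMENT_PAST_INEFFECTIVE"
    TREATMENT_PAST_NEGATIVE = "TREATMENT_PAST_NEGATIVE"
    TREATMENT_CURRENT = "TREATMENT_CURRENT"
    TREATMENT_SUGGESTED = "TREATMENT_SUGGESTED"
    TREATMENT = "TREATMENT"
    OTHER = "OTHER"


#: Categories whose single member acts as the root of a record.
ROOT_CATEGORIES = frozenset({Category.INQUIRY, Category.DEVELOPMENT})

#: Categories whose charts carry treatment events and outcomes.
TREATMENT_CATEGORIES = frozenset(
    {
        Category.TREATMENT_PAST_INEFFECTIVE,
        Category.TREATMENT_PAST_NEGATIVE,
        Category.TREATMENT_CURRENT,
        Category.TREATMENT_SUGGESTED,
        Category.TREATMENT,
    }
)


@dataclass(frozen=True)
class Chart:
    """An ordered scenario: lifelines, a linear event body and chaining links.

    ``activates`` is a list of ``(trigger_index, chart_name)`` pairs: when the
    body event at ``trigger_index`` is consumed, the named chart switches from
    inactive to active.  ``standalone`` charts start active without needing a
    link from the root.
    """

    name: str
    category: Category
    lifelines: frozenset[EntityRef]
    body: tuple[EventInstance, ...]
    activates: tuple[tuple[int, str], ...] = ()
    subcategory: Optional[str] = None
    standalone: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.category, Category):
            object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "lifelines", frozenset(self.lifelines))
        object.__setattr__(self, "body", tuple(self.body))
        object.__setattr__(
            self, "activates", tuple((int(i), c) for i, c in self.activates)
        )
        if not IDENTIFIER_RE.match(self.name):
            raise ValueError(f"chart name {self.name!r} is not an identifier")


@dataclass(frozen=True)
class Vocabulary:
    """Immutable name -> EventDecl map shared by all records of a database."""

    decls: dict[str, EventDecl] = field(default_factory=dict)

    def resolve(self, name: str) -> Optional[EventDecl]:
        return self.decls.get(name)

    def __contains__(self, name: str) -> bool:
        return name in self.decls

    def __len__(self) -> int:
        return len(self.decls)

    def __iter__(self) -> Iterator[EventDecl]:
        return iter(self.decls.values())


@dataclass(frozen=True)
class PatientRecord:
    """One patient's chart set, grouped by category, plus free-text metadata."""

    patient: EntityRef
    charts: tuple[Chart, ...]
    meta: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "charts", tuple(self.charts))

    def chart(self, name: str) -> Chart:
        for c in self.charts:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class ScenarioDB:
    """A database of patient records sharing one event vocabulary."""

    vocabulary: Vocabulary
    records: tuple[PatientRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def record(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient.id == patient_id:
                return r
        raise KeyError(patient_id)


@dataclass(frozen=True)
class Issue:
    """One validation finding: which chart/event broke which invariant."""

    code: str
    message: str
    chart: Optional[str] = None
    event_index: Optional[int] = None

    def __str__(self) -> str:
        where = self.chart or "<record>"
        if self.event_index is not None:
            where += f"[{self.event_index}]"
        return f"{where}: {self.code}: {self.message}"


def ensure_event_decl(vocab: Vocabulary, decl: EventDecl) -> Vocabulary:
    """Add *decl* to *vocab* if absent; idempotent for identical signatures.

    Mirrors the dynamically growing vocabulary: the first report of a new
    symptom registers its event, later reports reuse it.  Raises
    :class:`ArityConflict` if the name exists with a different kind or
    parameter signature.  The input vocabulary is never mutated.
    """
    existing = vocab.resolve(decl.name)
    if existing is None:
        return Vocabulary({**vocab.decls, decl.name: decl})
    if existing.kind == decl.kind and existing.params == decl.params:
        return vocab
    raise ArityConflict(
        f"event {decl.name!r} already declared with a different signature"
    )


def merge_vocabularies(*vocabs: Vocabulary) -> Vocabulary:
    """Union of vocabularies; conflicting signatures raise ArityConflict."""
    out = Vocabulary({})
    for v in vocabs:
        for decl in v:
            out = ensure_event_decl(out, decl)
    return out


def _check_event(
    vocab: Vocabulary, chart: Chart, idx: int, ev: EventInstance
) -> list[Issue]:
    issues: list[Issue] = []
    decl = vocab.resolve(ev.name)
    if decl is None:
        issues.append(
            Issue("unknown-event", f"event {ev.name!r} not in vocabulary", chart.name, idx)
        )
        return issues
    if len(ev.args) != decl.arity:
        issues.append(
            Issue(
                "arity-conflict",
                f"{ev.name} called with {len(ev.args)} args, declared {decl.arity}",
                chart.name,
                idx,
            )
        )
    else:
        for pos, (param, arg) in enumerate(zip(decl.params, ev.args)):
            err = check_value(param.ptype, arg)
            if err is not None:
                issues.append(
                    Issue(
                        "bad-arg-type",
                        f"{ev.name} arg {pos} ({param.name}): {err}",
                        chart.name,
                        idx,
                    )
                )
    for end, ref in (("source", ev.source), ("target", ev.target)):
        if ref not in chart.lifelines:
            issues.append(
                Issue(
                    "lifeline-missing",
                    f"{end} {ref.render()} is not a lifeline of {chart.name}",
                    chart.name,
                    idx,
                )
            )
    if ev.source == ev.target and ev.source.role is not Role.RECORD:
        issues.append(
            Issue(
                "self-message",
                f"{ev.name}: source equals target outside a RECORD self-annotation",
                chart.name,
                idx,
            )
        )
    return issues


def validate_record(db: ScenarioDB, record: PatientRecord) -> list[Issue]:
    """Check every structural invariant of *record* against *db*'s vocabulary.

    Findings are returned as data (an :class:`Issue` list), never raised; an
    empty list means the record is well-formed: a unique root chart reaches
    every non-standalone chart, the activation graph is acyclic, and every
    event resolves in the vocabulary with correctly typed arguments.
    """
    issues: list[Issue] = []
    if record.patient.role is not Role.PATIENT:
        issues.append(
            Issue("bad-patient-role", f"record patient has role {record.patient.role.value}")
        )

    names = [c.name for c in record.charts]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            issues.append(Issue("duplicate-chart-name", f"chart {n!r} declared twice"))
        seen.add(n)

    roots = [c for c in record.charts if c.category in ROOT_CATEGORIES]
    if len(roots) != 1:
        issues.append(
            Issue(
                "root-count",
                f"expected exactly one INQUIRY/DEVELOPMENT root chart, found {len(roots)}",
            )
        )

    graph = nx.DiGraph()
    graph.add_nodes_from(seen)
    for chart in record.charts:
        if not chart.body:
            issues.append(Issue("empty-body", "chart body must be non-empty", chart.name))
        for idx, ev in enumerate(chart.body):
            issues.extend(_check_event(db.vocabulary, chart, idx, ev))
        for trig, target in chart.activates:
            if not 0 <= trig < len(chart.body):
                issues.append(
                    Issue(
                        "bad-activation-index",
                        f"trigger index {trig} outside body of length {len(chart.body)}",
                        chart.name,
                    )
                )
            if target not in seen:
                issues.append(
                    Issue(
                        "dangling-activation",
                        f"activation target {target!r} names no chart in this record",
                        chart.name,
                    )
                )
            else:
                graph.add_edge(chart.name, target)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        issues.append(
            Issue("activation-cycle", f"activation links form a cycle: {cycle}")
        )
    elif len(roots) == 1:
        reachable = {roots[0].name} | nx.descendants(graph, roots[0].name)
        for chart in record.charts:
            if chart.name not in reachable and not chart.standalone:
                issues.append(
                    Issue(
                        "unreachable-chart",
                        "chart is neither reachable from the root nor standalone",
                        chart.name,
                    )
                )
    return issues


def validate_db(db: ScenarioDB) -> list[Issue]:
    """Validate every record plus database-level invariants (unique ids)."""
    issues: list[Issue] = []
    seen_ids: set[str] = set()
    for record in db.records:
        if record.patient.id in seen_ids:
            issues.append(
                Issue("duplicate-patient-id", f"patient id {record.patient.id!r} reused")
            )
        seen_ids.add(record.patient.id)
        issues.extend(validate_record(db, record))
    return issues


def chart_stats(record: PatientRecord) -> pd.DataFrame:
    """One row per chart: name, category, event count and distinct decl count."""
    rows = [
        {
            "chart": c.name,
            "category": c.category.value,
            "events": len(c.body),
            "distinct_decls": len({e.name for e in c.body}),
        }
        for c in record.charts
    ]
    return pd.DataFrame(rows, columns=["chart", "category", "events", "distinct_decls"])
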