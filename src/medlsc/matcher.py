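"""The "virtual patient" query: match reported conditions against a scenario
database and return the treatments each matched patient received, with their
recorded effectiveness.

A query is a set of event patterns (wildcard arguments allowed).  A record's
score is the fraction of patterns that match at least one event anywhere in
its charts — containment, not ordered sub-trace matching.  Effectiveness is
read off the structure of the record: the treatment-category of the chart a
medicine appears in, refined by explicit outcome events (``Ineffective``,
``NegativeEffect``, ``reportImprovement``/``Improvement``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .engine import event_matches
from .model import (
    Category,
    EventDecl,
    EventInstance,
    PatientRecord,
    ScenarioDB,
    Tag,
    TREATMENT_CATEGORIES,
    Vocabulary,
)


class Outcome(str, enum.Enum):
    """Recorded effectiveness of a treatment."""

    INEFFECTIVE = "INEFFECTIVE"
    NEGATIVE_EFFECT = "NEGATIVE_EFFECT"
    IMPROVEMENT = "IMPROVEMENT"
    CURRENT = "CURRENT"
    SUGGESTED = "SUGGESTED"


#: Category-implied default outcome for treatment charts.
_CATEGORY_OUTCOME = {
    Category.TREATMENT_PAST_INEFFECTIVE: Outcome.INEFFECTIVE,
    Category.TREATMENT_PAST_NEGATIVE: Outcome.NEGATIVE_EFFECT,
    Category.TREATMENT_CURRENT: Outcome.CURRENT,
    Category.TREATMENT_SUGGESTED: Outcome.SUGGESTED,
}

#: Outcome events that refine the category default.
_OUTCOME_EVENTS = {
    "Ineffective": Outcome.INEFFECTIVE,
    "NegativeEffect": Outcome.NEGATIVE_EFFECT,
    "Improvement": Outcome.IMPROVEMENT,
    "reportImprovement": Outcome.IMPROVEMENT,
}


@dataclass(frozen=True)
class Query:
    """A non-empty set of reported-condition patterns."""

    patterns: tuple[EventInstance, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patterns", tuple(self.patterns))
        if not self.patterns:
            raise ValueError("a query needs at least one pattern")


@dataclass
class MatchResult:
    """Outcome of matching one query against one patient record."""

    patient_id: str
    score: float
    matched: list[tuple[EventInstance, EventInstance, str]] = field(default_factory=list)
    treatments: list[tuple[EventInstance, Outcome]] = field(default_factory=list)
    novel: list[EventInstance] = field(default_factory=list)


def _chart_outcome(chart) -> Optional[Outcome]:
    outcome = _CATEGORY_OUTCOME.get(chart.category)
    for ev in chart.body:
        hit = _OUTCOME_EVENTS.get(ev.name)
        if hit is not None:
            outcome = hit
    return outcome


def record_treatments(
    record: PatientRecord, vocab: Vocabulary
) -> list[tuple[EventInstance, Outcome]]:
    """Treatment events (MEDICINE/PROCEDURE-tagged) of the record's
    treatment-category charts, each with its recorded outcome."""
    out: list[tuple[EventInstance, Outcome]] = []
    for chart in record.charts:
        if chart.category not in TREATMENT_CATEGORIES:
            continue
        outcome = _chart_outcome(chart)
        if outcome is None:
            continue
        for ev in chart.body:
            decl = vocab.resolve(ev.name)
            if decl is not None and decl.tag in (Tag.MEDICINE, Tag.PROCEDURE):
                out.append((ev, outcome))
    return out


def match_record(
    query: Query, record: PatientRecord, vocab: Vocabulary
) -> MatchResult:
    """Match every query pattern against all events of all charts.

    Score is ``|patterns with >= 1 match| / |patterns|``.  Patterns whose
    event name is absent from the vocabulary are reported in ``novel`` (as
    data, not an exception) and count as unmatched.
    """
    matched: list[tuple[EventInstance, EventInstance, str]] = []
    novel: list[EventInstance] = []
    n_hit = 0
    for pattern in query.patterns:
        if pattern.name not in vocab:
            novel.append(pattern)
            continue
        hit = False
        for chart in record.charts:
            for ev in chart.body:
                if event_matches(pattern, ev):
                    matched.append((pattern, ev, chart.name))
                    hit = True
        if hit:
            n_hit += 1
    return MatchResult(
        patient_id=record.patient.id,
        score=n_hit / len(query.patterns),
        matched=matched,
        treatments=record_treatments(record, vocab),
        novel=novel,
    )


def query_db(
    db: ScenarioDB, query: Query, min_score: float = 0.0
) -> list[MatchResult]:
    """Match against every record; keep results scoring at least *min_score*,
    sorted by score descending then patient id ascending (deterministic)."""
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    results = [match_record(query, r, db.vocabulary) for r in db.records]
    kept = [r for r in results if r.score >= min_score]
    kept.sort(key=lambda r: (-r.score, r.patient_id))
    return kept


def vocab_export(
    db: ScenarioDB, tag: Optional[Tag] = None
) -> list[EventDecl]:
    """Export vocabulary entries, optionally filtered by tag, sorted by name
    — e.g. the list of medicines known to the database."""
    decls = [d for d in db.vocabulary if tag is None or d.tag == tag]
    return sorted(decls, key=lambda d: d.name)
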