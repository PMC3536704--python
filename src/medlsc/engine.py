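"""Executable semantics: monitoring traces against charts, and play-out.

Each chart is a linear sequence of events with a *cut* — the index of the
next expected event once the chart is active.  Root charts (the single
INQUIRY/DEVELOPMENT chart) and standalone charts start active; every other
chart waits for an activation link to fire.

The step rule for an active chart and an incoming event:

* the event equals the body event at the cut (same declaration, same
  source/target roles, same arguments) — the cut advances, and any
  activation link anchored at that index fires;
* otherwise, if the event's declaration still occurs somewhere in the
  remaining body (the chart's residual alphabet), the chart is VIOLATED with
  reason "out of order" — the scenario promised a different continuation;
* events foreign to the remaining body are ignored.

A chart whose cut reaches the end of its body is COMPLETED.  Statuses only
ever move forward along INACTIVE -> ACTIVE -> {COMPLETED | VIOLATED}.

Play-out is the deterministic dual: repeatedly take the earliest-declared
active chart with remaining events, emit its expected event, and feed that
event back through the step rule (so concurrently active charts advance or
object exactly as a monitor would).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    WILDCARD,
    Chart,
    EventInstance,
    PatientRecord,
    ROOT_CATEGORIES,
    Vocabulary,
)

Trace = tuple[EventInstance, ...]


class UnknownEvent(Exception):
    """An event name failed to resolve in the vocabulary."""


class DeadlockReport(Exception):
    """Play-out produced an event that violates a concurrently active chart:
    two charts demand incompatible continuations."""


class Status(str, enum.Enum):
    INACTIVE = "INACTIVE"
    ACTIVE = "ACTIVE"
    COMPLETED = "COMPLETED"
    VIOLATED = "VIOLATED"


@dataclass
class ChartState:
    """Runtime state of one chart: status plus the cut index."""

    chart: str
    status: Status = Status.INACTIVE
    cut: int = 0
    reason: Optional[str] = None


@dataclass
class MonitorVerdict:
    """Final per-chart states after consuming a trace, with any violations
    as ``(step index, chart name, reason)`` triples."""

    states: dict[str, ChartState]
    consumed: int
    violations: list[tuple[int, str, str]] = field(default_factory=list)

    def status(self, chart: str) -> Status:
        return self.states[chart].status

    def completed(self) -> list[str]:
        return [n for n, s in self.states.items() if s.status is Status.COMPLETED]


def event_matches(
    pattern: EventInstance, event: EventInstance, vocab: Optional[Vocabulary] = None
) -> bool:
    """True iff *event* satisfies *pattern*.

    Declaration names and source/target roles must agree exactly (entity ids
    are deliberately not compared, so a pattern written against one patient
    matches the same scenario in another record).  Pattern arguments equal
    to :data:`~medlsc.model.WILDCARD` match anything.
    """
    if vocab is not None:
        for name in (pattern.name, event.name):
            if name not in vocab:
                raise UnknownEvent(name)
    if pattern.name != event.name:
        return False
    if pattern.source.role != event.source.role or pattern.target.role != event.target.role:
        return False
    if len(pattern.args) != len(event.args):
        return False
    return all(p is WILDCARD or p == a for p, a in zip(pattern.args, event.args))


def init_states(record: PatientRecord) -> dict[str, ChartState]:
    """Initial monitor states: roots and standalone charts active at cut 0."""
    states: dict[str, ChartState] = {}
    for chart in record.charts:
        active = chart.category in ROOT_CATEGORIES or chart.standalone
        states[chart.name] = ChartState(
            chart.name, Status.ACTIVE if active else Status.INACTIVE
        )
    return states


def step(
    states: dict[str, ChartState],
    record: PatientRecord,
    event: EventInstance,
    vocab: Optional[Vocabulary] = None,
) -> dict[str, ChartState]:
    """Advance all active charts of *record* by one incoming event.

    *states* is updated in place and returned.  Newly violated charts carry
    the violation reason on their state.
    """
    if vocab is not None and event.name not in vocab:
        raise UnknownEvent(event.name)
    pending: list[str] = []
    for chart in record.charts:
        st = states[chart.name]
        if st.status is not Status.ACTIVE:
            continue
        expected = chart.body[st.cut]
        if event_matches(expected, event):
            fired = st.cut
            st.cut += 1
            if st.cut == len(chart.body):
                st.status = Status.COMPLETED
            for trig, target in chart.activates:
                if trig == fired:
                    pending.append(target)
        elif any(e.name == event.name for e in chart.body[st.cut :]):
            st.status = Status.VIOLATED
            st.reason = (
                f"out of order: expected {expected.name} at cut {st.cut}, "
                f"saw {event.name}"
            )
    # activations apply after every chart has seen this event, so a newly
    # activated chart starts consuming at the *next* step regardless of
    # declaration order
    for target in pending:
        tgt = states.get(target)
        if tgt is not None and tgt.status is Status.INACTIVE:
            tgt.status = Status.ACTIVE
    return states


def monitor_trace(
    record: PatientRecord,
    trace: Sequence[EventInstance],
    vocab: Optional[Vocabulary] = None,
) -> MonitorVerdict:
    """Fold :func:`step` over *trace* and report the final verdict."""
    states = init_states(record)
    violations: list[tuple[int, str, str]] = []
    for i, event in enumerate(trace):
        if vocab is not None and event.name not in vocab:
            raise UnknownEvent(f"step {i}: {event.name}")
        before = {n for n, s in states.items() if s.status is Status.VIOLATED}
        step(states, record, event)
        for name, st in states.items():
            if st.status is Status.VIOLATED and name not in before:
                violations.append((i, name, st.reason or "violated"))
    return MonitorVerdict(states=states, consumed=len(trace), violations=violations)


def playout(record: PatientRecord, vocab: Optional[Vocabulary] = None) -> Trace:
    """Generate the canonical trace of *record* by superstep execution.

    Repeatedly selects the earliest chart in declaration order that is
    active with remaining events and emits its expected event, feeding the
    event through the step rule so activation links fire and concurrently
    active charts advance.  Deterministic for a fixed record.  Raises
    :class:`DeadlockReport` if an emission violates another active chart.
    """
    states = init_states(record)
    out: list[EventInstance] = []
    budget = sum(len(c.body) for c in record.charts) + 1
    while True:
        chosen: Optional[Chart] = None
        for chart in record.charts:
            st = states[chart.name]
            if st.status is Status.ACTIVE and st.cut < len(chart.body):
                chosen = chart
                break
        if chosen is None:
            break
        event = chosen.body[states[chosen.name].cut]
        out.append(event)
        if len(out) > budget:  # pragma: no cover - guarded impossibility
            raise DeadlockReport("no progress: emitted more events than exist")
        step(states, record, event, vocab)
        for name, st in states.items():
            if st.status is Status.VIOLATED:
                raise DeadlockReport(
                    f"emitting {event.name} for {chosen.name} violates {name}: {st.reason}"
                )
    return tuple(out)
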