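"""Brute-force oracle for chart monitoring, plus small random records.

The oracle classifies a trace per chart by an independent route: it first
derives each chart's activation step recursively from its parents'
consumption times, then scans the trace from that step with a direct cut
scan.  The engine under test instead folds an incremental step function
over the trace for all charts at once; agreement of the two routes over all
interleavings of chart bodies is the correctness check.
"""

from __future__ import annotations

import random
from typing import Iterator, Optional

from medlsc.model import (
    Category,
    Chart,
    EntityRef,
    EventDecl,
    EventInstance,
    EventKind,
    ParamSpec,
    PatientRecord,
    PType,
    ROOT_CATEGORIES,
    Role,
    ScenarioDB,
    Vocabulary,
)

_DOC = EntityRef(Role.DOCTOR, "d")
_PAT = EntityRef(Role.PATIENT, "p")
_REC = EntityRef(Role.RECORD, "p")
_ENDPOINTS = [(_DOC, _PAT), (_PAT, _DOC), (_DOC, _REC)]


def _eq(a: EventInstance, b: EventInstance) -> bool:
    return (
        a.name == b.name
        and a.source.role == b.source.role
        and a.target.role == b.target.role
        and a.args == b.args
    )


def oracle_verdict(record: PatientRecord, trace: tuple) -> dict[str, tuple[str, int]]:
    """Final ``{chart: (status, cut)}`` computed by per-chart scanning."""
    by_name = {c.name: c for c in record.charts}
    parents: dict[str, list[tuple[str, int]]] = {}
    for c in record.charts:
        for trig, target in c.activates:
            parents.setdefault(target, []).append((c.name, trig))
    memo: dict[str, tuple[str, int, dict[int, int]]] = {}

    def scan(name: str) -> tuple[str, int, dict[int, int]]:
        if name in memo:
            return memo[name]
        chart = by_name[name]
        act = activation_step(name)
        if act is None:
            memo[name] = ("INACTIVE", 0, {})
            return memo[name]
        cut, times, status = 0, {}, "ACTIVE"
        for t in range(act, len(trace)):
            ev = trace[t]
            if _eq(chart.body[cut], ev):
                times[cut] = t
                cut += 1
                if cut == len(chart.body):
                    status = "COMPLETED"
                    break
            elif any(e.name == ev.name for e in chart.body[cut:]):
                status = "VIOLATED"
                break
        memo[name] = (status, cut, times)
        return memo[name]

    def activation_step(name: str) -> Optional[int]:
        chart = by_name[name]
        if chart.category in ROOT_CATEGORIES or chart.standalone:
            return 0
        best: Optional[int] = None
        for pname, trig in parents.get(name, []):
            _, _, ptimes = scan(pname)
            if trig in ptimes:
                candidate = ptimes[trig] + 1
                best = candidate if best is None else min(best, candidate)
        return best

    return {c.name: scan(c.name)[:2] for c in record.charts}


def interleavings(bodies: tuple[tuple, ...]) -> Iterator[tuple]:
    """All merges of the given sequences preserving each internal order."""
    if all(not b for b in bodies):
        yield ()
        return
    for i, b in enumerate(bodies):
        if b:
            rest = bodies[:i] + (b[1:],) + bodies[i + 1 :]
            for tail in interleavings(rest):
                yield (b[0],) + tail


def interleaving_count(lengths: list[int]) -> int:
    from math import factorial

    total = factorial(sum(lengths))
    for l in lengths:
        total //= factorial(l)
    return total


_NAMES = ["EvA", "EvB", "EvC", "EvD"]


def oracle_vocabulary() -> Vocabulary:
    decls = {
        n: EventDecl(n, EventKind.GENERIC, (ParamSpec("v", PType.TEXT),))
        for n in _NAMES
    }
    return Vocabulary(decls)


def random_small_record(rng: random.Random) -> PatientRecord:
    """A record with <= 3 charts of <= 4 events, chart 0 the root, later
    charts activated by a random earlier chart at a random trigger index.
    Event names deliberately collide across charts to exercise the
    out-of-order rule."""
    lifelines = frozenset({_DOC, _PAT, _REC})
    n_charts = rng.randint(1, 3)
    charts: list[Chart] = []
    for ci in range(n_charts):
        n_events = rng.randint(1, 4)
        body = []
        for _ in range(n_events):
            src, tgt = rng.choice(_ENDPOINTS)
            body.append(
                EventInstance(rng.choice(_NAMES), src, tgt, (rng.choice(["x", "y"]),))
            )
        charts.append(
            Chart(
                name=f"C{ci}",
                category=Category.DEVELOPMENT if ci == 0 else Category.OTHER,
                lifelines=lifelines,
                body=tuple(body),
            )
        )
    # wire activations: each non-root chart hangs off one earlier chart
    for ci in range(1, n_charts):
        parent = rng.randrange(ci)
        trig = rng.randrange(len(charts[parent].body))
        charts[parent] = Chart(
            name=charts[parent].name,
            category=charts[parent].category,
            lifelines=charts[parent].lifelines,
            body=charts[parent].body,
            activates=charts[parent].activates + ((trig, f"C{ci}"),),
        )
    return PatientRecord(patient=_PAT, charts=tuple(charts))


def random_small_db(rng: random.Random) -> ScenarioDB:
    return ScenarioDB(oracle_vocabulary(), (random_small_record(rng),))
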