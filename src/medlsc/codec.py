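"""Readers/writers for `medlsc/1` documents, trace logs and query files.

The document format is plain JSON with a fixed schema::

    {
      "format": "medlsc/1",
      "vocabulary": [{"name": ..., "kind": ..., "params": [...], "tag": ...}],
      "patients":   [{"patient": "PATIENT:id", "meta": {...}, "charts": [...]}]
    }

Serialization is deterministic (fixed key order, declarations sorted by
name, records and chart bodies in insertion order), so an identical database
always produces byte-identical files.  Unknown top-level keys are rejected;
per-object extension keys are accepted and round-tripped only under an
``x-`` prefix.

Trace logs are text, one event per line::

    12 PATIENT:patientX -> DOCTOR:drG ReportSurgery("appendix Removal", 1997)

with a strictly increasing sequence number, ``#`` comments and blank lines
ignored, TEXT arguments JSON-quoted and integers bare.  Query files use the
same event syntax (sequence number optional) and allow ``*`` in argument
positions as a wildcard.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Sequence, Union

from .model import (
    WILDCARD,
    Category,
    Chart,
    EntityRef,
    EventDecl,
    EventInstance,
    EventKind,
    ParamSpec,
    PatientRecord,
    PType,
    ScenarioDB,
    Tag,
    Vocabulary,
    ensure_event_decl,
    validate_db,
)

FORMAT_TAG = "medlsc/1"

#: An event trace is simply an ordered tuple of event instances.
Trace = tuple[EventInstance, ...]

IOFailure = OSError


class ParseError(Exception):
    """Malformed document or trace line; carries position context."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(Exception):
    """A database failed structural validation; carries the Issue list."""

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__(
            "; ".join(str(i) for i in self.issues[:5])
            + (f" (+{len(self.issues) - 5} more)" if len(self.issues) > 5 else "")
        )


# --------------------------------------------------------------------------
# JSON document serialization


def _extra_items(obj: dict) -> list[tuple[str, object]]:
    return sorted(obj.items())


def _decl_to_json(decl: EventDecl) -> dict:
    out: dict = {
        "name": decl.name,
        "kind": decl.kind.value,
        "params": [{"name": p.name, "ptype": p.ptype.value} for p in decl.params],
    }
    if decl.tag is not None:
        out["tag"] = decl.tag.value
    return out


def _event_to_json(ev: EventInstance) -> dict:
    return {
        "event": ev.name,
        "source": ev.source.render(),
        "target": ev.target.render(),
        "args": list(ev.args),
    }


def _chart_to_json(chart: Chart) -> dict:
    out: dict = {
        "name": chart.name,
        "category": chart.category.value,
        "lifelines": sorted(l.render() for l in chart.lifelines),
        "body": [_event_to_json(e) for e in chart.body],
        "activates": [[i, c] for i, c in chart.activates],
    }
    if chart.subcategory is not None:
        out["subcategory"] = chart.subcategory
    if chart.standalone:
        out["standalone"] = True
    out.update(_extra_items(chart.extra))
    return out


def _record_to_json(record: PatientRecord) -> dict:
    out: dict = {
        "patient": record.patient.render(),
        "meta": {k: record.meta[k] for k in sorted(record.meta)},
        "charts": [_chart_to_json(c) for c in record.charts],
    }
    out.update(_extra_items(record.extra))
    return out


def serialize_db(db: ScenarioDB) -> str:
    """Deterministic text rendering of *db* as a `medlsc/1` document."""
    doc = {
        "format": FORMAT_TAG,
        "vocabulary": [
            _decl_to_json(db.vocabulary.decls[name])
            for name in sorted(db.vocabulary.decls)
        ],
        "patients": [_record_to_json(r) for r in db.records],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"


def _take(obj: dict, known: Sequence[str], where: str) -> dict:
    """Split off ``x-`` extension keys; reject any other unknown key."""
    extra = {}
    for key in obj:
        if key in known:
            continue
        if key.startswith("x-"):
            extra[key] = obj[key]
        else:
            raise ParseError(f"unknown key {key!r} in {where}")
    return extra


def _parse_decl(obj: dict) -> EventDecl:
    if not isinstance(obj, dict):
        raise ParseError(f"vocabulary entry must be an object, got {obj!r}")
    _take(obj, ("name", "kind", "params", "tag"), "vocabulary entry")
    try:
        params = tuple(
            ParamSpec(p["name"], PType(p["ptype"])) for p in obj.get("params", [])
        )
        return EventDecl(
            name=obj["name"],
            kind=EventKind(obj["kind"]),
            params=params,
            tag=Tag(obj["tag"]) if obj.get("tag") is not None else None,
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"bad vocabulary entry {obj.get('name', '?')!r}: {exc}") from exc


def _parse_event(obj: dict, where: str) -> EventInstance:
    _take(obj, ("event", "source", "target", "args"), where)
    try:
        args = obj.get("args", [])
        if not isinstance(args, list):
            raise ValueError("args must be a list")
        for a in args:
            if not isinstance(a, (str, int)) or isinstance(a, bool):
                raise ValueError(f"unsupported argument {a!r}")
        return EventInstance(
            name=obj["event"],
            source=EntityRef.parse(obj["source"]),
            target=EntityRef.parse(obj["target"]),
            args=tuple(args),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"bad event in {where}: {exc}") from exc


def _parse_chart(obj: dict, where: str) -> Chart:
    extra = _take(
        obj,
        ("name", "category", "lifelines", "body", "activates", "subcategory", "standalone"),
        where,
    )
    try:
        name = obj["name"]
        return Chart(
            name=name,
            category=Category(obj["category"]),
            lifelines=frozenset(EntityRef.parse(t) for t in obj.get("lifelines", [])),
            body=tuple(
                _parse_event(e, f"{where}/{name}") for e in obj.get("body", [])
            ),
            activates=tuple((int(i), str(c)) for i, c in obj.get("activates", [])),
            subcategory=obj.get("subcategory"),
            standalone=bool(obj.get("standalone", False)),
            extra=extra,
        )
    except ParseError:
        raise
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"bad chart in {where}: {exc}") from exc


def _parse_record(obj: dict, index: int) -> PatientRecord:
    where = f"patients[{index}]"
    extra = _take(obj, ("patient", "meta", "charts"), where)
    try:
        meta = obj.get("meta", {})
        if not isinstance(meta, dict):
            raise ValueError("meta must be an object")
        return PatientRecord(
            patient=EntityRef.parse(obj["patient"]),
            charts=tuple(_parse_chart(c, where) for c in obj.get("charts", [])),
            meta=dict(meta),
            extra=extra,
        )
    except ParseError:
        raise
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"bad record {where}: {exc}") from exc


def _infer_decl(vocab: Vocabulary, ev: EventInstance) -> EventDecl:
    """Infer a signature for an undeclared event from its first instance.

    Strings become TEXT.  Integers become INT, except values in [1900, 2100]
    at a position where some existing declaration carries a YEAR-typed
    parameter named ``year`` — those become YEAR (avoids silently mistyping
    arbitrary integers as years).
    """
    params = []
    for pos, arg in enumerate(ev.args):
        if isinstance(arg, str):
            params.append(ParamSpec(f"p{pos}", PType.TEXT))
        else:
            ptype = PType.INT
            if isinstance(arg, int) and 1900 <= arg <= 2100:
                for decl in vocab:
                    if (
                        pos < decl.arity
                        and decl.params[pos].name == "year"
                        and decl.params[pos].ptype is PType.YEAR
                    ):
                        ptype = PType.YEAR
                        break
            name = "year" if ptype is PType.YEAR else f"p{pos}"
            params.append(ParamSpec(name, ptype))
    kind = EventKind.GENERIC if params else EventKind.SPECIFIC
    return EventDecl(ev.name, kind, tuple(params))


def parse_db(text: str, strict: bool = True) -> ScenarioDB:
    """Parse a `medlsc/1` document from *text*; see :func:`load_db`."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"not valid JSON: {exc.msg}", line=exc.lineno) from exc
    if not isinstance(doc, dict):
        raise ParseError("document root must be an object")
    _take(doc, ("format", "vocabulary", "patients"), "document")
    tag = doc.get("format")
    if tag != FORMAT_TAG:
        raise ParseError(f"unsupported format tag {tag!r} (expected {FORMAT_TAG!r})")

    vocab = Vocabulary({})
    for entry in doc.get("vocabulary", []):
        try:
            vocab = ensure_event_decl(vocab, _parse_decl(entry))
        except Exception as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(str(exc)) from exc
    records = tuple(
        _parse_record(obj, i) for i, obj in enumerate(doc.get("patients", []))
    )

    if not strict:
        # Auto-register undeclared events, mirroring the dynamically growing
        # vocabulary of the interactive play-in workflow.
        for record in records:
            for chart in record.charts:
                for ev in chart.body:
                    if ev.name not in vocab:
                        vocab = ensure_event_decl(vocab, _infer_decl(vocab, ev))

    db = ScenarioDB(vocabulary=vocab, records=records)
    if strict:
        issues = validate_db(db)
        if issues:
            raise ValidationError(issues)
    return db


def load_db(path: Union[str, Path], strict: bool = True) -> ScenarioDB:
    """Read a `medlsc/1` document.

    With ``strict`` on (the default) any validation Issue raises
    :class:`ValidationError`; with ``strict`` off, event names missing from
    the vocabulary are auto-registered by inferring a signature from their
    first instance, and structural issues are tolerated.
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_db(text, strict=strict)


def save_db(db: ScenarioDB, path: Union[str, Path]) -> None:
    """Write *db* deterministically; refuses (and writes nothing) if invalid."""
    issues = validate_db(db)
    if issues:
        raise ValidationError(issues)
    Path(path).write_text(serialize_db(db), encoding="utf-8")


# --------------------------------------------------------------------------
# Trace logs and query files

_EVENT_RE = re.compile(
    r"""^\s*
        (?P<source>[A-Z]+:[A-Za-z0-9_.-]+)\s*->\s*
        (?P<target>[A-Z]+:[A-Za-z0-9_.-]+)\s+
        (?P<name>[A-Za-z][A-Za-z0-9_]*)\s*
        \((?P<args>.*)\)\s*$""",
    re.VERBOSE,
)


def render_arg(arg: object) -> str:
    if arg is WILDCARD:
        return "*"
    if isinstance(arg, str):
        return json.dumps(arg, ensure_ascii=False)
    return str(arg)


def render_event(ev: EventInstance) -> str:
    args = ", ".join(render_arg(a) for a in ev.args)
    return f"{ev.source.render()} -> {ev.target.render()} {ev.name}({args})"


def _split_args(text: str, line: Optional[int]) -> list[str]:
    parts: list[str] = []
    buf: list[str] = []
    in_string = False
    escaped = False
    for ch in text:
        if in_string:
            buf.append(ch)
            if escaped:
                escaped = False
            elif ch == "\\":
                escaped = True
            elif ch == '"':
                in_string = False
        elif ch == '"':
            in_string = True
            buf.append(ch)
        elif ch == ",":
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if in_string:
        raise ParseError("unterminated string in argument list", line)
    parts.append("".join(buf))
    return parts


def _parse_arg(token: str, line: Optional[int]) -> object:
    token = token.strip()
    if token == "*":
        return WILDCARD
    if token.startswith('"'):
        try:
            return json.loads(token)
        except json.JSONDecodeError as exc:
            raise ParseError(f"bad text argument {token!r}: {exc.msg}", line) from exc
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"bad argument {token!r}", line) from None


def parse_event_text(text: str, line: Optional[int] = None) -> EventInstance:
    """Parse one rendered event, e.g. ``DOCTOR:d -> RECORD:p CFS()``."""
    m = _EVENT_RE.match(text)
    if m is None:
        raise ParseError(f"malformed event {text.strip()!r}", line)
    raw = m.group("args").strip()
    args: tuple = ()
    if raw:
        args = tuple(_parse_arg(tok, line) for tok in _split_args(raw, line))
    try:
        source = EntityRef.parse(m.group("source"))
        target = EntityRef.parse(m.group("target"))
    except ValueError as exc:
        raise ParseError(str(exc), line) from exc
    return EventInstance(m.group("name"), source, target, args)


def read_trace(path: Union[str, Path]) -> Trace:
    """Read a trace log; sequence numbers must be strictly increasing."""
    events: list[EventInstance] = []
    last_seq = -1
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = re.match(r"^(\d+)\s+(.*)$", stripped)
        if m is None:
            raise ParseError(f"expected '<seq> <event>', got {stripped!r}", lineno)
        seq = int(m.group(1))
        if seq <= last_seq:
            raise ParseError(f"sequence number {seq} not greater than {last_seq}", lineno)
        last_seq = seq
        events.append(parse_event_text(m.group(2), lineno))
    return tuple(events)


def write_trace(trace: Sequence[EventInstance], path: Union[str, Path]) -> None:
    lines = [f"{i} {render_event(ev)}" for i, ev in enumerate(trace)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_query(path: Union[str, Path]) -> tuple[EventInstance, ...]:
    """Read query patterns: trace-line syntax, sequence number optional,
    ``*`` allowed in argument positions."""
    patterns: list[EventInstance] = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = re.match(r"^(\d+)\s+(.*)$", stripped)
        text = m.group(2) if m else stripped
        patterns.append(parse_event_text(text, lineno))
    return tuple(patterns)
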