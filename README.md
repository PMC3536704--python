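# medlsc

**Scenario-chart encoding, execution and querying of medical interview
narratives.**

Medical records are long free-text narratives; mining them systematically —
especially for diagnoses of exclusion such as Chronic Fatigue Syndrome
(CFS), which rest entirely on self-reported history — requires a formal,
executable representation. `medlsc` encodes a doctor–patient interview as an
*object model*: three entities (the **Doctor**, the **Patient** and the
patient's **Record**) exchange typed events, and ordered event sequences are
grouped into modular **charts**, one per narrative category (personal
background, diseases, injuries, surgeries, abnormal responses, fatigue
history, past/current/suggested treatments). The chart formalism is a
deliberately linear subset of Live Sequence Charts (LSC): each chart is a
total order of events with a *cut* marking the next expected event, and
*activation links* by which progress in one chart switches further charts on
(e.g. a CFS diagnosis event activating the treatment charts).

The package provides:

* **`medlsc.model`** — typed domain objects (entities, a growing event
  vocabulary with GENERIC/SPECIFIC declarations, charts, patient records,
  scenario databases) and structural validation that returns findings as
  data (`Issue` lists), including activation-graph acyclicity and
  root-reachability. The ongoing-condition convention encodes "never
  recovered" as a duration of `-1` weeks.
* **`medlsc.codec`** — a deterministic, round-trip-stable JSON document
  format (`medlsc/1`) for vocabularies plus patient records, a plain-text
  trace-log format (one event per line, strictly increasing sequence
  numbers), and query files with `*` wildcards.
* **`medlsc.engine`** — executable semantics: `playout` generates the
  canonical trace of a record deterministically; `monitor_trace` folds a
  trace through every chart, advancing cuts, firing activation links, and
  flagging out-of-order events as violations.
* **`medlsc.matcher`** — the "virtual patient" query: match a set of
  reported-condition patterns against the database and return, per patient,
  the fraction of conditions matched and the treatments on file with their
  recorded effectiveness (ineffective / negative effect / improvement /
  current / suggested).
* **`medlsc.fixtures`** — the two worked cases shipped as `medlsc/1`
  documents (a synthetic gut-surgery-to-CFS case, and the `patientX`
  admission interview transcribed event-by-event), plus a seeded
  synthetic-cohort generator.

## Worked example

```python
from medlsc import chart_stats, playout, monitor_trace, Status
from medlsc.fixtures import patientx_db

db = patientx_db()
record = db.records[0]
print(chart_stats(record).head(3).to_string(index=False))
trace = playout(record, db.vocabulary)
verdict = monitor_trace(record, trace, db.vocabulary)
print(len(trace), len(verdict.completed()), len(verdict.violations))
```

prints

```
                    chart              category  events  distinct_decls
            DoctorInquiry               INQUIRY       7               7
GeneralPersonalBackground   PERSONAL_BACKGROUND       5               5
     PsychiatryBackground PSYCHIATRY_BACKGROUND       3               1
54 13 0
```

— the root inquiry chart routes through the four background categories
(seven events, including the final CFS diagnosis), the personal background
holds the interview's five facts, the psychiatric background its three
episodes; play-out emits all 54 events of the 13 reachable charts and the
monitor completes every chart with zero violations.

The virtual-patient query (`examples/virtual_patient_query.py`) reports a
surgery-related fatigue cause plus an unmatched psychiatric condition and
gets back:

```
patientX: score 0.50 (1 matching events)
  treatment DOCTOR:doctor -> RECORD:patientX Aleve() -> INEFFECTIVE
  treatment DOCTOR:doctor -> RECORD:patientX Tramadol() -> NEGATIVE_EFFECT
  treatment DOCTOR:doctor -> RECORD:patientX Advair(2003) -> CURRENT
```

i.e. half the reported conditions were previously recorded for patientX,
whose file lists an ineffective Aleve course, a Tramadol course with
negative effects, and Advair as current medication.

Each script in `examples/` demonstrates one capability end to end:
inspecting a record, play-out + monitoring, querying, and cohort synthesis.
A thin CLI wraps the same operations:

```bash
medlsc stats db.json                 # per-chart event counts
medlsc simulate db.json --out t.log  # play-out to a trace log
medlsc validate db.json --trace t.log
medlsc match db.json query.txt --min-score 0.5
medlsc vocab db.json --tag MEDICINE
medlsc synth --seed 7 --n-patients 100 --out cohort.json
```

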