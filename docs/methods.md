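# Methods

## The object model

An interview narrative is formalised as interactions among three entities:
the *Doctor*, the *Patient*, and the *RecordPatient* (the patient's file).
Every interaction is an **event**: a named, typed message from one entity to
another, e.g. `Disease("Rinderpest", 5, 3)` — the patient reports a disease
of that type, diagnosed at age 5, lasting 3 weeks. Event names are
case-sensitive identifiers; free text ("Shoulder Dislocation",
"Temperature 39°C") lives in TEXT arguments, never in names, so the
vocabulary stays machine-checkable.

The **vocabulary** declares each event name once with a fixed parameter
signature. *Generic* events describe a parameterised class of occurrences
(a fatigue-state change with state and year); *specific* events name one
concrete item, typically a medicine (`Aleve()`, `Advair(year)`). The
vocabulary grows monotonically: `ensure_event_decl` registers a new symptom
the first time any patient reports it and is idempotent thereafter;
redeclaring a name with a different signature is an error. Parameter types
carry domain constraints: YEAR ∈ [1900, 2100], AGE_YEARS ∈ [0, 130], and
DURATION_WEEKS is nonnegative **or exactly −1**, the sentinel meaning the
patient never recovered.

A **chart** is one narrative scenario: a set of lifelines and a linear body
of events, with `activates` links `(trigger index, chart name)` that switch
another chart from inactive to active when the trigger event is consumed.
A **record** is one patient's chart set; exactly one chart of category
INQUIRY or DEVELOPMENT is the root, and every chart must be reachable from
it through activation links (or be explicitly standalone). The activation
graph must be acyclic (checked via networkx).

## The LSC subset

Full LSC semantics includes per-lifeline partial orders, hot/cold
modalities, conditions and symbolic instances. This package deliberately
restricts to the fragment the encoded interviews actually use:

* **charts are total orders** — every encoded chart is a linear event list,
  so partial-order cuts collapse to a single integer cut;
* **no temperatures** — no event is marked hot or cold; instead every
  post-activation body event is mandatory-in-order, and the violation rule
  below approximates hot violations. This strictness is a feature for a
  curation tool: encoding mistakes surface as violations rather than being
  silently skipped;
* no conditions, assignments, forbidden fragments, or time constraints.

## Execution semantics

Monitoring folds a step rule over the trace. For each *active* chart and
incoming event:

1. if the event equals the body event at the cut (same declaration, same
   source/target roles, same arguments), the cut advances; reaching the end
   completes the chart;
2. otherwise, if the event's declaration still occurs in the remaining body
   (the chart's residual alphabet), the chart is **violated** ("out of
   order") — the scenario promised a different continuation;
3. events foreign to the remaining body are ignored.

Activation links fire *after* all charts have processed the current event,
so a newly activated chart begins consuming at the next step regardless of
chart declaration order; statuses move only forward along
INACTIVE → ACTIVE → {COMPLETED | VIOLATED}.

**Play-out** is the deterministic dual: repeatedly select the
earliest-declared active chart with remaining events, emit its expected
event, and feed it back through the step rule. Tie-breaking by declaration
order makes play-out reproducible without timestamps. If an emitted event
violates a concurrently active chart, play-out raises a deadlock report:
two charts demanded incompatible continuations. Correctness is checked two
ways: a self-consistency property (monitoring a record's own play-out
completes every chart with zero violations) and agreement with an
independent brute-force oracle that classifies *every* interleaving of
chart bodies for small random records (≤ 3 charts × ≤ 4 events) by
per-chart recursive scanning.

### Activation topology of the interview fixture

The admission-interview record (`patientX`) encodes thirteen charts. The
root `DoctorInquiry` activates the four background charts at the
corresponding routing events (general, medical, psychiatry, fatigue), and
the `MedicalBackground` chart fans out to its four subcategory charts. The
four treatment charts are **chained in their listed order** (ineffective →
negative effect → current → suggested), with the chain rooted at the CFS
diagnosis event. A simultaneous activation of all four at the diagnosis
event is the other defensible reading, but it is incompatible with the
strict out-of-order rule: `Prescription()` occurs in two treatment charts,
so whichever chart ran first would violate the other. Chaining preserves
the narrative order, keeps the strict rule, and makes play-out and
monitoring mutually consistent.

### Fixture fidelity

Event listings are transcribed verbatim, including internal inconsistencies
of the source narrative, which are logged in the record's
`meta["paper_discrepancies"]` rather than silently fixed: the car-accident
age argument of 9 (prose says 24), the Depression fatigue-cause year 1987
(prose says 1997), and `NegativeEffect("Sweating")` printed with one
argument but encoded with the ongoing duration −1 to satisfy its
two-parameter signature. The suggested-treatment chart is described as
alternative continuations; the linear subset encodes the
patient-consideration path. Both fixtures are committed as `medlsc/1`
documents so the codec runs on every load; a test pins the committed bytes
to the programmatic builders.

## Document and trace formats

`medlsc/1` is JSON with a closed schema: unknown top-level keys are
rejected, unknown per-object keys are accepted (and round-tripped) only
under an `x-` prefix. Serialization is deterministic — fixed key order,
declarations sorted by name, records in insertion order — so equal
databases yield byte-identical files. Trace logs are UTF-8 text, one event
per line with a strictly increasing sequence number; TEXT arguments are
JSON-quoted (so `"Temperature 39°C"` survives), integers are bare. Query
files reuse the event syntax with `*` as an argument wildcard. With strict
loading off, undeclared events are auto-registered from their first
instance: strings infer TEXT; integers infer INT, except values in
[1900, 2100] at a position where an existing declaration carries a
YEAR-typed parameter named `year`, which infer YEAR — a deliberate guard
against silently mistyping arbitrary integers as years.

## The virtual-patient matcher

No scoring formula is prescribed by the scenario formalism, so the package
uses the simplest monotone one and documents it as its own choice: a
query's score against a record is the fraction of patterns matching at
least one event anywhere in the record (containment, not ordered sub-trace
matching — matching in temporal order is a possible extension). Pattern
matching compares declaration names, source/target *roles* (not entity
ids, so one patient's pattern applies to another's record) and non-wildcard
arguments. Patterns absent from the vocabulary are returned as *novel*
events — data, not an exception — and count as unmatched. Results are
ranked by score descending, ties broken lexicographically by patient id.

Treatment effectiveness is operationalised structurally, since the source
records no numeric scale: the chart category implies a default outcome
(past-ineffective → INEFFECTIVE, past-negative → NEGATIVE_EFFECT, current →
CURRENT, suggested → SUGGESTED), refined by explicit outcome events in the
chart body (`Ineffective`, `NegativeEffect`, `reportImprovement` /
`Improvement`). Treatment events are those tagged MEDICINE or PROCEDURE in
the vocabulary.

## The synthetic-cohort generator

`generate_cohort` emulates a future multi-patient database at the level the
matcher and engine care about: per record, Poisson-distributed counts of
diseases, injuries and surgeries (defaults 1.5 / 1.0 / 0.8 per record —
background burdens comparable to the worked interview case), years uniform
in 1980–2010, ~20% of conditions ongoing (duration −1), and a single
treatment chart whose outcome is drawn with probabilities
`p_ineffective = 0.25`, `p_negative = 0.15`, `p_improvement = 0.4`
(remainder: no treatment recorded). Every generated record validates and
plays out to completion by construction; generation is driven by one
`numpy` generator seed, so equal configurations serialize byte-identically.

What the generator does **not** emulate: narrative free text, temporal
correlation between background events and outcomes, co-morbidity structure,
or realistic CFS epidemiology. Passing tests therefore demonstrate the
machinery (validation, execution, round-tripping, matching, parameter
recovery), not clinical realism.

## Numerical and scale choices

* Brute-force oracle comparison enumerates all interleavings for 500 random
  records of ≤ 3 charts × ≤ 4 events (≈ 10⁵ traces, a few seconds); codec
  round-trip identity is checked on 1000 random databases; outcome-recovery
  uses n = 200 records against a binomial 99% band (±0.12 around 0.5) and
  rate recovery uses n = 1000 against 3 Poisson standard errors.
* Degenerate inputs: empty traces leave roots active at cut 0; an empty
  record yields an empty statistics table; a zero-patient cohort is valid.
* All hypothesis property tests are derandomised; every other random draw
  is explicitly seeded.

## Known limitations

* Alternatives, loops and interleaving *within* one chart are inexpressible
  (linear bodies only).
* The out-of-order rule keys on declaration names over the remaining body;
  two charts that are simultaneously active and share a declaration will
  conflict — the interview encoding avoids this by chaining, and play-out
  reports it as a deadlock rather than guessing.
* Matching is containment-based; it ignores event order and counts
  (a pattern matching five events scores the same as one matching once).
* The CLI's strict mode re-validates rather than streaming; documents are
  read whole (fine for interview-scale data).
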