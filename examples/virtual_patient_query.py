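"""The virtual-patient query: report conditions, get prior treatments back.

Builds a two-patient database (the admission interview plus the synthetic
case), queries it with two reported conditions — a surgery-related fatigue
cause and a psychiatric condition the database has never seen for this
query — and prints each matching patient with the fraction of conditions
matched and the treatments on file with their recorded effectiveness.
"""

from medlsc import WILDCARD, EntityRef, EventInstance, Role
from medlsc.codec import render_event
from medlsc.fixtures import paper_db
from medlsc.matcher import Query, query_db

db = paper_db()
pat = EntityRef(Role.PATIENT, "me")
doc = EntityRef(Role.DOCTOR, "clinic")

query = Query(
    (
        EventInstance("ReportFatigueReasons", pat, doc, ("Surgery", WILDCARD)),
        EventInstance("ReportPsychiatryCondition", pat, doc, ("Schizophrenia", WILDCARD)),
    )
)

for result in query_db(db, query, min_score=0.0):
    print(f"{result.patient_id}: score {result.score:.2f} "
          f"({len(result.matched)} matching events)")
    for ev, outcome in result.treatments:
        print(f"  treatment {render_event(ev)} -> {outcome.value}")

# patientX matches the surgery-related fatigue cause (1 of 2 patterns, 0.50)
# and returns Aleve (ineffective), Tramadol (negative effect), Advair (current).
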