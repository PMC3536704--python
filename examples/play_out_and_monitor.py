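"""Execute the synthetic gut-surgery case and monitor its own trace.

Play-out emits the canonical event trace of the record (the Development
chart runs to the CFS diagnosis, which activates the Treatment chart);
feeding that trace back through the monitor must complete every chart with
zero violations.  Deleting an event demonstrates how the monitor reports an
incomplete scenario.
"""

from medlsc import Status, monitor_trace, playout
from medlsc.codec import render_event
from medlsc.fixtures import synthetic_db

db = synthetic_db()
record = db.records[0]

trace = playout(record, db.vocabulary)
print(f"play-out emitted {len(trace)} events:")
for i, ev in enumerate(trace):
    print(f"  {i:2d} {render_event(ev)}")

verdict = monitor_trace(record, trace, db.vocabulary)
print("\nmonitor verdict (all charts should be COMPLETED):")
for name, state in verdict.states.items():
    print(f"  {name}: {state.status.value} (cut {state.cut})")
print(f"violations: {len(verdict.violations)}")

# drop the improvement report: the Treatment chart stalls one step short
pruned = trace[:-1]
stalled = monitor_trace(record, pruned, db.vocabulary)
state = stalled.states["Treatment"]
print(
    f"\nwithout the final improvement report the Treatment chart is "
    f"{state.status.value} at cut {state.cut} of {len(record.chart('Treatment').body)}"
)
assert state.status is Status.ACTIVE
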