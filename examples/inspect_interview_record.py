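"""Load the packaged admission-interview record and summarise its charts.

Prints one row per scenario chart: the narrative category, how many events
the chart holds and how many distinct vocabulary entries they use.  The
counts mirror the interview itself — e.g. five personal-background facts,
three psychiatric episodes, two diseases (one ongoing, duration -1).
"""

from medlsc import chart_stats
from medlsc.fixtures import build_patientx

record = build_patientx()
table = chart_stats(record)
print(table.to_string(index=False))
print()
print(f"total events across {len(table)} charts: {table['events'].sum()}")
print("discrepancy log:", record.meta["paper_discrepancies"][:80], "...")
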