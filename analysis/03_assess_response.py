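"""Classify per-lesion response with all six assessment methods.

RANO on each of the five size measurements (volumetric thresholds for
volumes, unidimensional for diameters) plus the clinician-style assessment
that references the previous time point and can call radio-necrosis.
"""

import json
from collections import Counter

import pandas as pd

from bmrano.pipeline import assess_cohort

from common import RESULTS, SCRATCH, get_cohort

cohort = get_cohort()
sequences = assess_cohort(cohort)

rows = [
    {"lesion_id": s.lesion_id, "time_days": t, "method": m, "category": str(c)}
    for m, seqs in sequences.items()
    for s in seqs
    for t, c in zip(s.times, s.categories)
]
table = pd.DataFrame(rows)
table.to_csv(SCRATCH / "assessments.csv", index=False)

dist = {
    m: dict(Counter(str(c) for s in seqs for c in s.categories))
    for m, seqs in sequences.items()
}
(RESULTS / "response_distribution.json").write_text(json.dumps(dist, indent=2))

print(f"{len(table)} follow-up assessments across {len(sequences)} methods.")
for m, d in dist.items():
    total = sum(d.values())
    parts = ", ".join(f"{k} {100 * v / total:.0f}%" for k, v in sorted(d.items()))
    print(f"  {m:>14}: {parts}")
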