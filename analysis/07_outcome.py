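"""One-year outcome predictability: how early each method sees the final
response.

The 1-year response is the category of the first follow-up after 365 days;
the detection day is when that category is first observed. Methods that
anticipate the definitive outcome earlier are more clinically useful.
"""

import json

from bmrano.outcome import cohort_outcome_summary
from bmrano.pipeline import assess_cohort

from common import RESULTS, get_cohort

cohort = get_cohort()
sequences = assess_cohort(cohort)
summary, pvals = cohort_outcome_summary(sequences)

summary.to_csv(RESULTS / "outcome_summary.csv", index=False)
pvals.round(4).to_csv(RESULTS / "outcome_pairwise_p.csv")

print(f"Lesions with > 1 year of follow-up: {int(summary.n_lesions.max())}.")
print(summary.round(1).to_string(index=False))
best = summary.loc[summary.mean_detection_day.idxmin(), "method"]
print(f"Earliest mean detection of the 1-year response: {best}.")
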