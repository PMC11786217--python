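"""Generate the default synthetic cohort and describe its structure.

Emulated study conditions: a few hundred lesions over a few dozen patients,
baseline + 1-6 follow-ups at ~75-day intervals, paired manual/automatic
contours, biased manual diameter readings, ~11% radio-necrosis labels.
"""

import json

import numpy as np

from common import RESULTS, SCRATCH, SEED, get_cohort

cohort = get_cohort()
table = cohort.table()
table.to_csv(SCRATCH / "cohort.csv", index=False)

followup_spans = [t.times[-1] for t in cohort.trajectories]
n_timepoints = [len(t.observations) for t in cohort.trajectories]
summary = {
    "seed": SEED,
    "n_patients": table.patient_id.nunique(),
    "n_lesions": cohort.n_lesions,
    "n_studies": int(table.groupby(["patient_id", "time_days"]).ngroups),
    "timepoints_per_lesion_mean": float(np.mean(n_timepoints)),
    "followup_span_days_mean": float(np.mean(followup_spans)),
    "followup_span_days_sd": float(np.std(followup_spans)),
    "radionecrosis_fraction": float(np.mean([t.radionecrosis for t in cohort.trajectories])),
    "trajectory_kinds": {
        k: int(sum(t.kind == k for t in cohort.trajectories))
        for k in sorted({t.kind for t in cohort.trajectories})
    },
}
(RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2))

print(f"Cohort (seed {SEED}): {summary['n_lesions']} lesions, "
      f"{summary['n_patients']} patients, {summary['n_studies']} imaging studies.")
print(f"Follow-up span {summary['followup_span_days_mean']:.0f} +/- "
      f"{summary['followup_span_days_sd']:.0f} days; "
      f"{100 * summary['radionecrosis_fraction']:.1f}% lesions labelled radio-necrosis.")
print(f"Full table -> {SCRATCH / 'cohort.csv'}; summary -> results/cohort_summary.json")
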