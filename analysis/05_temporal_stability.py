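"""Stability of size measurements and assessments across time.

Hypothesis: a standard post-treatment size evolution is monotone, so the
absolute Spearman correlation between time and measured size reflects
measurement quality, and the rate of response-category changes between
consecutive follow-ups reflects assessment churn.
"""

import json

from bmrano.pipeline import temporal_stability

from common import RESULTS, SCRATCH, get_cohort

cohort = get_cohort()
table, summary = temporal_stability(cohort)
table.to_csv(SCRATCH / "stability_temporal.csv", index=False)
(RESULTS / "stability_temporal.json").write_text(json.dumps(summary, indent=2))

print(f"{summary['n_lesions']} lesions with >= 3 time points.")
print("Mean |Spearman(time, size)|:",
      {m: round(v, 3) for m, v in summary["mean_abs_spearman"].items()})
print("Pooled response-change rate:",
      {m: round(v, 3) for m, v in summary["pooled_change_rate"].items()})
p = summary["wilcoxon_spearman_p"].get("vol-manseg|diam-manseg")
print(f"Volumes track time more monotonically than diameters "
      f"(Wilcoxon vol-manseg vs diam-manseg: p = {p:.1e}).")
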