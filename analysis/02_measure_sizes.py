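"""Measure lesion sizes with the five methods and quantify systematic bias.

Expected structure: manual diameter readings are systematically smaller
than contour-derived diameters (multiplicative bias ~0.75), while manual
and automatic contours give near-identical volumes.
"""

import json

import numpy as np

from bmrano.pipeline import measure_cohort, size_observation_table
from bmrano.stability import unpaired_difference_test

from common import RESULTS, SCRATCH, get_cohort

cohort = get_cohort()
measurements = measure_cohort(cohort)
measurements.to_csv(SCRATCH / "measurements.csv", index=False)

wide = size_observation_table(cohort)
summary = {
    "n_observations": len(wide),
    "mean_size": {
        m: float(wide[m].mean())
        for m in ("diam-manseg", "diam-autoseg", "man-diam", "vol-manseg", "vol-autoseg")
    },
    "volume_corr_manual_vs_auto": float(
        np.corrcoef(wide["vol-manseg"], wide["vol-autoseg"])[0, 1]
    ),
    "mandiam_vs_contour_diam_wilcoxon_p": float(
        unpaired_difference_test(wide["man-diam"], wide["diam-manseg"])
    ),
}
(RESULTS / "size_summary.json").write_text(json.dumps(summary, indent=2))

ms = summary["mean_size"]
print(f"{summary['n_observations']} fully measured lesion-time observations.")
print(f"Mean diameters: man-diam {ms['man-diam']:.2f} mm < "
      f"diam-manseg {ms['diam-manseg']:.2f} mm ~ diam-autoseg {ms['diam-autoseg']:.2f} mm "
      f"(rank-sum p = {summary['mandiam_vs_contour_diam_wilcoxon_p']:.2e}).")
print(f"Manual vs automatic contour volumes: r = "
      f"{summary['volume_corr_manual_vs_auto']:.4f} (near-identical).")
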