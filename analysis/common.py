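"""Shared setup for the numbered analysis drivers.

All drivers run on the same default ~200-lesion synthetic cohort at a fixed
seed, regenerate it deterministically in memory (cheap), write concise
summaries under ``results/`` and bulky per-lesion tables or figures under
``scratch/analysis/``.
"""

from pathlib import Path

from bmrano.synthetic import default_analysis_config, generate_cohort

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"


def get_cohort():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    return generate_cohort(default_analysis_config(seed=SEED))
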