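# bmrano — volumetric vs unidimensional response assessment for brain metastases

After stereotactic radiosurgery, brain metastases are followed on serial MRI
and each lesion's response is classified with the RANO-BM criteria from its
**longest axial diameter**: CR on disappearance, PR on a ≥30% decrease vs
baseline, PD on a ≥20% increase vs the nadir (the smallest size recorded up
to the assessment, baseline included), SD otherwise. With 3D lesion
contours available — drawn manually or produced by a segmentation model —
the same rules can instead be applied to **volumes**, using thresholds
extrapolated to a sphere:

```
PR_vol = 1 − (1 − 0.30)³ = 65.7%   volume decrease
PD_vol = (1 + 0.20)³ − 1 = 72.8%   volume increase
```

This package implements that comparison as a tested pipeline for
researchers in quantitative neuro-oncology imaging: size measurement from
3D binary masks (voxel-count volume, in-plane Feret axial diameter),
unidimensional / volumetric / clinician-style response classification,
stability analyses under contour rotation (emulating patient repositioning)
and across time (monotonicity of size trajectories), inter-method agreement
statistics (Pearson, Lin's CCC, Cohen's κ, PABAK, the Pearson–Filon test
for dependent non-overlapping correlations), and one-year outcome
predictability. Because per-patient imaging data of this kind are not
public, everything runs on a seeded synthetic longitudinal cohort generator
that reproduces the statistical structure the analyses assume (paired
manual/automatic contours with sawtooth vs smooth boundary noise, biased
manual diameter readings, radio-necrosis labels, monotone and
pseudo-progressing trajectories).

## Layout

- `src/bmrano/` — the library: `mask_ops` (geometry), `synthetic` (cohort
  generator), `response` (RANO classifiers), `stability`, `agreement`,
  `outcome`, `pipeline` (stage functions), `io`/`cli` (NIfTI/CSV boundary
  and the `bmrano` command).
- `analysis/` — numbered drivers (`01_simulate_cohort.py` …
  `07_outcome.py`) that run each stage on the default ~200-lesion cohort,
  print what they find and write summaries under `results/`.
- `scripts/acceptance.py` — recomputes the reference quantities (below).

## Worked example

```python
from bmrano import (RanoThresholds, SizeSeries, classify_rano,
                    volumetric_thresholds_from_diameter)

print(volumetric_thresholds_from_diameter(0.30, 0.20))
# (0.657, 0.7279999999999998)   -> the 65.7% / 72.8% volumetric thresholds

diam = SizeSeries("L1", "diam-manseg", times=(0, 60, 120), values=(10.0, 9.0, 11.0))
print(classify_rano(diam, RanoThresholds()).categories)
# (<Category.SD: 'SD'>, <Category.PD: 'PD'>)  -> 11 mm is +22% over the 9 mm nadir
```

Running the full pipeline on the default synthetic cohort
(`python analysis/04_rotation_stability.py`) prints, among other things:

```
163 lesions rotated over 21 angles.
Mean CoV: {'vol-autoseg': 0.007, 'vol-manseg': 0.0067, 'diam-autoseg': 0.0287, 'diam-manseg': 0.0297}
Change rate: {'vol-autoseg': 0.037, 'vol-manseg': 0.055, 'diam-autoseg': 0.209, 'diam-manseg': 0.196}
Volumes are markedly more stable than diameters (Wilcoxon vol vs diam, manseg: p = 1.0e-22; McNemar: p = 3.0e-04)
```

i.e. under ±20° rotations the coefficient of variation of cube-root volume
is ~4× smaller than that of the axial diameter, and rotation flips the
RANO category of ~20% of lesions when assessed by diameter but only ~4–6%
when assessed by volume — the core argument for volumetric response
assessment.

The same cohort can be driven from the shell:

```bash
bmrano all --seed 1 --outdir out/   # simulate -> measure -> assess -> analyses
```

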