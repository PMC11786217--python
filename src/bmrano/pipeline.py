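"""End-to-end analysis stages over a cohort.

Ties the modules together: measure sizes from the contours, classify
responses, run the rotation and temporal stability analyses, the agreement
analysis and the one-year-outcome analysis. Both the numbered analysis
drivers and the command-line interface call these functions; they operate
on in-memory :class:`~bmrano.synthetic.Cohort` objects and return pandas
tables / plain dicts ready to serialise.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .agreement import (
    confusion,
    agreement_summary,
    lin_ccc,
    pearson_filon_test,
    pearson_r,
)
from .mask_ops import RotationSpec, cube_root_size, longest_axial_diameter, rotate_mask, volume_mm3
from .response import (
    RanoThresholds,
    ResponseSequence,
    SizeSeries,
    classify_clinician_style,
    classify_rano,
    exclude_radionecrosis,
)
from .stability import (
    consecutive_change_count,
    paired_difference_test,
    paired_rate_test,
    pooled_change_rate,
    temporal_monotonicity,
)
from .synthetic import Cohort, LesionTrajectory

MEASUREMENT_METHODS = ("vol-manseg", "vol-autoseg", "diam-manseg", "diam-autoseg", "man-diam")
CONTOUR_METHODS = MEASUREMENT_METHODS[:4]
ASSESSMENT_FOR_MEASUREMENT = {
    "vol-manseg": "RANOv-manseg",
    "vol-autoseg": "RANOv-autoseg",
    "diam-manseg": "RANOu-manseg",
    "diam-autoseg": "RANOu-autoseg",
    "man-diam": "RANOu-mandiam",
}


def _available_methods(traj: LesionTrajectory) -> tuple[str, ...]:
    if traj.has_manual_reading and all(
        o.is_cr or (o.manual_diameter_mm or 0) > 0 for o in traj.observations
    ) and (traj.observations[0].manual_diameter_mm or 0) > 0:
        return MEASUREMENT_METHODS
    return CONTOUR_METHODS


def measure_cohort(cohort: Cohort) -> pd.DataFrame:
    """Size measurements: one row per lesion x time x method."""
    rows = []
    for traj in cohort.trajectories:
        for method in _available_methods(traj):
            series = traj.size_series(method)
            for t, v in zip(series.times, series.values):
                rows.append(
                    {
                        "patient_id": traj.patient_id,
                        "lesion_id": traj.lesion_id,
                        "time_days": t,
                        "method": method,
                        "size_value": v,
                        "units": "mm3" if method.startswith("vol") else "mm",
                    }
                )
    return pd.DataFrame(rows)


def _thresholds_for(method: str) -> RanoThresholds:
    return RanoThresholds.volumetric() if method.startswith("vol") else RanoThresholds()


def assess_cohort(cohort: Cohort) -> dict[str, list[ResponseSequence]]:
    """Response sequences for the 5 RANO variants plus the clinician style."""
    out: dict[str, list[ResponseSequence]] = {
        name: [] for name in ASSESSMENT_FOR_MEASUREMENT.values()
    }
    out["cliAssess-u"] = []
    for traj in cohort.trajectories:
        for method in _available_methods(traj):
            series = traj.size_series(method)
            seq = classify_rano(series, _thresholds_for(method))
            out[ASSESSMENT_FOR_MEASUREMENT[method]].append(
                ResponseSequence(seq.lesion_id, ASSESSMENT_FOR_MEASUREMENT[method], seq.times, seq.categories)
            )
        if "man-diam" in _available_methods(traj):
            series = traj.size_series("man-diam")
            match = tuple(o.t1t2_match for o in traj.observations[1:])
            out["cliAssess-u"].append(classify_clinician_style(series, match))
    return out


def radionecrosis_labels(cohort: Cohort) -> dict[str, bool]:
    return {t.lesion_id: t.radionecrosis for t in cohort.trajectories}


# ---------------------------------------------------------------------------
# rotation stability


def rotation_stability(
    cohort: Cohort, spec: RotationSpec | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-lesion rotation CoVs and response-change flags, plus pooled tests.

    Lesions that are CR at the last time point are excluded (an empty mask
    cannot be rotated). For each remaining lesion the last-time-point
    contour of each source is rotated once over the angle set; the same
    rotated masks feed the diameter and cube-root-volume CoVs and the
    RANO response-change flags (baseline and nadir stay unrotated).
    Returns (per-lesion table, summary dict with pooled statistics and
    pairwise Wilcoxon/McNemar p-values).
    """
    spec = spec or RotationSpec()
    angles = list(spec.angles)
    i0 = angles.index(0)
    rows = []
    for traj in cohort.trajectories:
        last = traj.observations[-1]
        if last.is_cr:
            continue
        # lesions shrunk below the diameter's resolution (no slice with
        # two voxels) cannot support a rotation CoV; skip like CR lesions
        if any(
            longest_axial_diameter(m) == 0 for m in last.masks.values()
        ):
            continue
        row: dict = {"lesion_id": traj.lesion_id}
        for source in ("manseg", "autoseg"):
            mask = last.masks["manual" if source == "manseg" else "automatic"]
            rotated = [rotate_mask(mask, a, spec.axes) for a in angles]
            diams = np.array([longest_axial_diameter(m) for m in rotated])
            vols = np.array([volume_mm3(m) for m in rotated])
            cbrt = np.array([cube_root_size(v) for v in vols])
            row[f"cov_diam-{source}"] = diams.std(ddof=1) / diams.mean()
            row[f"cov_vol-{source}"] = cbrt.std(ddof=1) / cbrt.mean()
            for meas, sizes in (("diam", diams), ("vol", vols)):
                series = traj.size_series(f"{meas}-{source}")
                thr = _thresholds_for(f"{meas}-{source}")

                def cat(size: float):
                    vals = series.values[:-1] + (float(size),)
                    s = SizeSeries(series.lesion_id, series.method, series.times, vals)
                    return classify_rano(s, thr).categories[-1]

                ref = cat(sizes[i0])
                row[f"change_{meas}-{source}"] = bool(any(cat(s) != ref for s in sizes))
        rows.append(row)
    table = pd.DataFrame(rows)

    methods = ["vol-autoseg", "vol-manseg", "diam-autoseg", "diam-manseg"]
    summary: dict = {
        "n_lesions": len(table),
        "angles": angles,
        "axes": spec.axes,
        "mean_cov": {m: float(table[f"cov_{m}"].mean()) for m in methods},
        "median_cov": {m: float(table[f"cov_{m}"].median()) for m in methods},
        "change_rate": {m: float(table[f"change_{m}"].mean()) for m in methods},
        "wilcoxon_cov_p": {},
        "mcnemar_change_p": {},
    }
    for ma, mb in itertools.combinations(methods, 2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary["wilcoxon_cov_p"][f"{ma}|{mb}"] = paired_difference_test(
                table[f"cov_{ma}"], table[f"cov_{mb}"]
            )
        summary["mcnemar_change_p"][f"{ma}|{mb}"] = paired_rate_test(
            table[f"change_{ma}"], table[f"change_{mb}"]
        )
    return table, summary


# ---------------------------------------------------------------------------
# temporal stability


def temporal_stability(cohort: Cohort) -> tuple[pd.DataFrame, dict]:
    """Monotonicity of size in time and response churn across follow-ups.

    Uses lesions with at least 3 time points; the paired method comparison
    keeps the intersection of lesions measurable by all methods compared.
    Spearman correlations are computed per size-measurement method; change
    rates per assessment method, pooled over all consecutive follow-up
    pairs.
    """
    rows = []
    for traj in cohort.trajectories:
        if len(traj.observations) < 3:
            continue
        row: dict = {"lesion_id": traj.lesion_id}
        for method in _available_methods(traj):
            series = traj.size_series(method)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row[f"spearman_{method}"] = temporal_monotonicity(series)
            seq = classify_rano(series, _thresholds_for(method))
            changes, pairs = consecutive_change_count(seq.categories)
            row[f"changes_{ASSESSMENT_FOR_MEASUREMENT[method]}"] = changes
            row[f"pairs_{ASSESSMENT_FOR_MEASUREMENT[method]}"] = pairs
        rows.append(row)
    table = pd.DataFrame(rows)

    spearman_cols = [c for c in table.columns if c.startswith("spearman_")]
    contour_methods = [c.removeprefix("spearman_") for c in spearman_cols]
    summary: dict = {
        "n_lesions": len(table),
        "mean_abs_spearman": {
            m: float(table[f"spearman_{m}"].mean()) for m in contour_methods
        },
        "pooled_change_rate": {},
        "wilcoxon_spearman_p": {},
        "mcnemar_change_p": {},
    }
    assess_methods = [
        ASSESSMENT_FOR_MEASUREMENT[m] for m in MEASUREMENT_METHODS if f"changes_{ASSESSMENT_FOR_MEASUREMENT[m]}" in table
    ]
    for am in assess_methods:
        sub = table.dropna(subset=[f"changes_{am}"])
        summary["pooled_change_rate"][am] = pooled_change_rate(
            list(zip(sub[f"changes_{am}"].astype(int), sub[f"pairs_{am}"].astype(int)))
        )
    for ma, mb in itertools.combinations(contour_methods, 2):
        sub = table.dropna(subset=[f"spearman_{ma}", f"spearman_{mb}"])
        if len(sub) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary["wilcoxon_spearman_p"][f"{ma}|{mb}"] = paired_difference_test(
                sub[f"spearman_{ma}"], sub[f"spearman_{mb}"]
            )
    for ma, mb in itertools.combinations(assess_methods, 2):
        sub = table.dropna(subset=[f"changes_{ma}", f"changes_{mb}"])
        flags_a, flags_b = [], []
        for _, r in sub.iterrows():
            n_pairs = int(r[f"pairs_{ma}"])
            # expand per consecutive-pair occurrences; paired per (lesion, pair)
            ca, cb = int(r[f"changes_{ma}"]), int(r[f"changes_{mb}"])
            flags_a.extend([True] * ca + [False] * (n_pairs - ca))
            flags_b.extend([True] * cb + [False] * (n_pairs - cb))
        if flags_a:
            summary["mcnemar_change_p"][f"{ma}|{mb}"] = paired_rate_test(flags_a, flags_b)
    return table, summary


# ---------------------------------------------------------------------------
# agreement


def size_observation_table(cohort: Cohort) -> pd.DataFrame:
    """Wide per-(lesion, time) table of all 5 size measurements.

    Only observations where every method is available and the lesion is
    present (nonzero truth) are kept — the paired-intersection handling.
    """
    rows = []
    for traj in cohort.trajectories:
        if _available_methods(traj) != MEASUREMENT_METHODS:
            continue
        series = {m: traj.size_series(m) for m in MEASUREMENT_METHODS}
        for i, obs in enumerate(traj.observations):
            if obs.is_cr:
                continue
            row = {"lesion_id": traj.lesion_id, "time_days": obs.time_days}
            for m in MEASUREMENT_METHODS:
                row[m] = series[m].values[i]
            rows.append(row)
    return pd.DataFrame(rows)


def agreement_analysis(cohort: Cohort) -> dict:
    """Correlation/CCC matrices, the Pearson-Filon comparison and kappas.

    * Pearson and CCC between the 3 diameter measures and between the 2
      volume measures, pooled over aligned (lesion, time) observations.
    * Pearson-Filon test of corr(diameter, cube-root volume) for manual vs
      automatic contours — the same lesions measured both ways.
    * Confusion matrices with percent agreement / kappa / PABAK for every
      assessment-method pair, radio-necrosis lesions excluded.
    """
    table = size_observation_table(cohort)
    diam_methods = ["diam-manseg", "diam-autoseg", "man-diam"]
    vol_methods = ["vol-manseg", "vol-autoseg"]

    def corr_matrix(methods, fn):
        out = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
        for a, b in itertools.combinations(methods, 2):
            out.loc[a, b] = out.loc[b, a] = fn(table[a].values, table[b].values)
        return out

    result: dict = {
        "n_observations": len(table),
        "pearson_diameters": corr_matrix(diam_methods, pearson_r),
        "ccc_diameters": corr_matrix(diam_methods, lin_ccc),
        "pearson_volumes": corr_matrix(vol_methods, pearson_r),
        "ccc_volumes": corr_matrix(vol_methods, lin_ccc),
    }

    cbrt_man = np.array([cube_root_size(v) for v in table["vol-manseg"]])
    cbrt_auto = np.array([cube_root_size(v) for v in table["vol-autoseg"]])
    r_man = pearson_r(table["diam-manseg"].values, cbrt_man)
    r_auto = pearson_r(table["diam-autoseg"].values, cbrt_auto)
    z, p = pearson_filon_test(
        table["diam-autoseg"].values, cbrt_auto, table["diam-manseg"].values, cbrt_man
    )
    result["diam_vol_correlation"] = {
        "manual": r_man,
        "automatic": r_auto,
        "pearson_filon_z": z,
        "pearson_filon_p": p,
    }

    sequences = assess_cohort(cohort)
    labels = radionecrosis_labels(cohort)
    filtered: dict[str, list[ResponseSequence]] = {
        method: exclude_radionecrosis(seqs, labels)[0] for method, seqs in sequences.items()
    }
    n_rn = sum(labels.values())
    result["radionecrosis_exclusion"] = {
        "n_excluded": n_rn,
        "fraction": n_rn / len(labels) if labels else 0.0,
    }

    result["response_agreement"] = {}
    for ma, mb in itertools.combinations(sorted(filtered), 2):
        if not filtered[ma] or not filtered[mb]:
            continue
        try:
            cm = confusion(filtered[ma], filtered[mb])
        except ValueError:
            continue
        result["response_agreement"][f"{ma}|{mb}"] = agreement_summary(cm)
    return result
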