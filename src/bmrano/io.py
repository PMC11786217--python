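"""NIfTI and table I/O at the pipeline boundary.

Masks travel as NIfTI files whose affine is the single source of orientation
truth; on read they are conformed to the RAS convention with axis 2 =
inferior-superior, and anisotropic or non-1mm grids are resampled to 1 mm
isotropic by nearest-neighbour (logged). Between stages everything else is
CSV/JSON — inspectable and diffable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mask_ops import Mask3D, resample_mask
from .synthetic import Cohort

log = logging.getLogger("bmrano")

COHORT_COLUMNS = [
    "patient_id",
    "lesion_id",
    "time_days",
    "contour_source",
    "mask_path",
    "manual_diameter_mm",
    "radiologist_label",
    "excluded_radionecrosis",
]


def write_mask(mask: Mask3D, path: str | Path) -> None:
    """Write a mask as NIfTI; the affine encodes spacing and origin (RAS)."""
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def read_mask(path: str | Path, auto_resample: bool = True) -> Mask3D:
    """Load a NIfTI mask, conform to RAS, and enforce 1 mm isotropic spacing.

    A file on an anisotropic (or non-1mm) grid is resampled to 1 mm
    isotropic by nearest-neighbour with a warning, unless
    ``auto_resample=False`` in which case the native spacing is kept.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)  # RAS, axis 2 = inferior-superior
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt / unreadable file
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    mask = Mask3D(data > 0, spacing, origin)
    if auto_resample and not np.allclose(spacing, 1.0):
        log.warning("mask %s has spacing %s; resampling to 1 mm isotropic", path.name, spacing)
        mask = resample_mask(mask, 1.0)
    return mask


def write_cohort(cohort: Cohort, outdir: str | Path, write_masks: bool = True) -> Path:
    """Write a cohort table (CSV) and optionally one NIfTI per mask.

    Returns the path of the cohort CSV. The table has one row per
    lesion x time x contour source; CR time points have no contour and a
    null mask path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask_dir = outdir / "masks"
    rows = []
    for traj in cohort.trajectories:
        for obs in traj.observations:
            sources = sorted(obs.masks) if obs.masks else [None]
            for src in sources:
                mask_path = None
                if src is not None and write_masks:
                    mask_path = mask_dir / f"{traj.lesion_id}_t{int(obs.time_days):04d}_{src}.nii.gz"
                    write_mask(obs.masks[src], mask_path)
                    mask_path = str(mask_path.relative_to(outdir))
                rows.append(
                    {
                        "patient_id": traj.patient_id,
                        "lesion_id": traj.lesion_id,
                        "time_days": obs.time_days,
                        "contour_source": src,
                        "mask_path": mask_path,
                        "manual_diameter_mm": obs.manual_diameter_mm,
                        "radiologist_label": obs.radiologist_label,
                        "excluded_radionecrosis": traj.radionecrosis,
                    }
                )
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    csv_path = outdir / "cohort.csv"
    table.to_csv(csv_path, index=False)
    return csv_path


def validate_cohort_table(table: pd.DataFrame) -> None:
    """Schema check for a cohort CSV; raises with the offending row number."""
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    for i, row in table.iterrows():
        if pd.isna(row["patient_id"]) or pd.isna(row["lesion_id"]):
            raise ValueError(f"cohort table row {i}: missing patient/lesion id")
        if pd.isna(row["time_days"]) or float(row["time_days"]) < 0:
            raise ValueError(f"cohort table row {i}: invalid time_days")


def write_manifest(path: str | Path, stage: str, inputs: list, outputs: list, config: dict, seed: int) -> None:
    """Stage manifest: inputs, outputs, config hash and seed, for provenance."""
    payload = {
        "stage": stage,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "config_hash": hex(hash(json.dumps(config, sort_keys=True, default=str)) & 0xFFFFFFFF),
        "config": config,
        "seed": seed,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
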