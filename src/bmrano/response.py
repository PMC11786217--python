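"""Per-lesion treatment-response classification from size series.

Implements the unidimensional RANO rules for brain metastases (RANOu), their
volumetric counterpart (RANOv) with thresholds extrapolated from diameters to
a sphere, and the clinician-style assessment that references the *previous*
time point and can call radio-necrosis on growth with a gado-T1/T2 mismatch.

Categories
----------
CR  disappearance of the lesion (size exactly 0)
PR  decrease of at least ``pr_decrease`` relative to the baseline size
PD  increase of at least ``pd_increase`` relative to the nadir (the smallest
    size at any time point up to and including the assessed one, baseline
    included)
SD  neither
RN  radio-necrosis (clinician-style only; growth with gado-T1/T2 mismatch)

When the PR and PD rules fire simultaneously (possible because they use
different references), PD takes precedence. After a CR the nadir is 0 and any
regrowth is classified PD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Category",
    "SizeSeries",
    "RanoThresholds",
    "ResponseSequence",
    "volumetric_thresholds_from_diameter",
    "classify_rano",
    "classify_clinician_style",
    "exclude_radionecrosis",
]

_REL_TOL = 1e-9  # "at least 30%" includes exactly 30% despite float rounding


class Category(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    RN = "RN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SizeSeries:
    """One size-measurement method applied along a lesion trajectory.

    ``times`` are days since treatment, strictly increasing, with the first
    entry the baseline scan; ``values`` are sizes (mm for diameters, mm^3 for
    volumes) with 0 encoding lesion disappearance. The baseline size must be
    positive — a lesion has to exist to be followed.
    """

    lesion_id: str
    method: str
    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        values = tuple(float(v) for v in self.values)
        if len(times) != len(values):
            raise ValueError("times and values must have equal length")
        if len(times) < 1:
            raise ValueError("series needs at least a baseline observation")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(v < 0 for v in values):
            raise ValueError("sizes must be non-negative")
        if values[0] <= 0:
            raise ValueError("baseline size must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def n_followups(self) -> int:
        return len(self.times) - 1


@dataclass(frozen=True)
class RanoThresholds:
    """Relative-change thresholds for PR and PD.

    Defaults are the unidimensional RANO values (30% diameter decrease for
    PR, 20% diameter increase for PD). Use :meth:`volumetric` for series of
    volumes.
    """

    pr_decrease: float = 0.30
    pd_increase: float = 0.20

    def __post_init__(self) -> None:
        if not (0 < self.pr_decrease < 1):
            raise ValueError("pr_decrease must lie in (0, 1)")
        if self.pd_increase <= 0:
            raise ValueError("pd_increase must be positive")

    @classmethod
    def volumetric(cls, pr_decrease: float = 0.30, pd_increase: float = 0.20) -> "RanoThresholds":
        """Thresholds for volume series, extrapolated from diameter thresholds."""
        pr, pd = volumetric_thresholds_from_diameter(pr_decrease, pd_increase)
        return cls(pr, pd)


@dataclass(frozen=True)
class ResponseSequence:
    """Ordered response categories per follow-up for one lesion and method.

    The baseline carries no category, so ``len(categories) == n_followups``
    and ``times`` are the follow-up days.
    """

    lesion_id: str
    method: str
    times: tuple[float, ...]
    categories: tuple[Category, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.categories):
            raise ValueError("one category per follow-up time required")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(
            self, "categories", tuple(Category(c) for c in self.categories)
        )


def volumetric_thresholds_from_diameter(
    pr_decrease: float, pd_increase: float
) -> tuple[float, float]:
    """Extrapolate diameter thresholds to volume thresholds via a sphere.

    A sphere's volume scales with the cube of its diameter, so a fractional
    diameter change ``d`` maps to the volume change ``(1+d)^3 - 1``. The RANO
    defaults (0.30 decrease, 0.20 increase) map to a 65.7% volume decrease
    and a 72.8% volume increase.

    >>> volumetric_thresholds_from_diameter(0.30, 0.20)
    (0.657, 0.7280000000000002)
    """
    if not (0 <= pr_decrease < 1) or pd_increase < 0:
        raise ValueError("thresholds out of range")
    return (1 - (1 - pr_decrease) ** 3, (1 + pd_increase) ** 3 - 1)


def classify_rano(series: SizeSeries, thresholds: RanoThresholds) -> ResponseSequence:
    """Classify each follow-up of a size series under the RANO rules.

    PR references the baseline; PD references the nadir — the smallest value
    across all time points up to and including the assessed one (baseline
    included). Categories at follow-up t therefore never depend on later
    observations. PD takes precedence when both rules fire, and any regrowth
    after a disappearance (nadir 0) is PD.
    """
    baseline = series.values[0]
    categories: list[Category] = []
    for i in range(1, len(series.values)):
        v = series.values[i]
        if v == 0:
            categories.append(Category.CR)
            continue
        nadir = min(series.values[: i + 1])
        if nadir == 0:
            categories.append(Category.PD)  # regrowth after disappearance
        elif v >= (1 + thresholds.pd_increase) * nadir * (1 - _REL_TOL):
            categories.append(Category.PD)
        elif v <= (1 - thresholds.pr_decrease) * baseline * (1 + _REL_TOL):
            categories.append(Category.PR)
        else:
            categories.append(Category.SD)
    return ResponseSequence(series.lesion_id, series.method, series.times[1:], tuple(categories))


def classify_clinician_style(
    diams: SizeSeries,
    t1t2_match: tuple[bool | None, ...],
) -> ResponseSequence:
    """Clinician-style assessment referencing the previous time point.

    Each follow-up is compared with the *previous* longest diameter: CR on
    disappearance, PR on a >=30% decrease, PD on a >=20% increase with a
    gado-T1/T2 match, radio-necrosis (RN) on such an increase with a
    mismatch, SD otherwise. ``t1t2_match`` gives one flag per follow-up; it
    may be None where no qualifying growth occurs, but a missing flag at a
    growth step is an error.
    """
    if len(t1t2_match) != diams.n_followups:
        raise ValueError("one t1t2_match flag per follow-up required")
    categories: list[Category] = []
    for i in range(1, len(diams.values)):
        prev, v = diams.values[i - 1], diams.values[i]
        match = t1t2_match[i - 1]
        if v == 0:
            categories.append(Category.CR)
            continue
        if prev == 0:
            grows = True  # regrowth from disappearance: treat as qualifying growth
        else:
            change = v / prev - 1
            grows = change >= 0.20 * (1 - _REL_TOL)
            if not grows:
                if change <= -0.30 * (1 - _REL_TOL):
                    categories.append(Category.PR)
                else:
                    categories.append(Category.SD)
                continue
        if match is None:
            raise ValueError(
                f"lesion {diams.lesion_id}: growth at follow-up {i} needs a "
                "gado-T1/T2 match flag"
            )
        categories.append(Category.PD if match else Category.RN)
    return ResponseSequence(diams.lesion_id, "cliAssess-u", diams.times[1:], tuple(categories))


@dataclass(frozen=True)
class ExclusionReport:
    n_total: int
    n_excluded: int

    @property
    def fraction(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0


def exclude_radionecrosis(
    sequences: list[ResponseSequence],
    labels: dict[str, bool],
) -> tuple[list[ResponseSequence], ExclusionReport]:
    """Drop lesions ever labelled radio-necrosis from cross-method comparison.

    Radio-necrosis is not a RANO category, so lesions carrying the label
    cannot be compared against the automated assessments; the whole lesion
    is removed. Returns the kept sequences and an exclusion report with the
    count and fraction of distinct excluded lesions.
    """
    lesion_ids = {s.lesion_id for s in sequences}
    excluded = {lid for lid in lesion_ids if labels.get(lid, False)}
    kept = [s for s in sequences if s.lesion_id not in excluded]
    return kept, ExclusionReport(n_total=len(lesion_ids), n_excluded=len(excluded))
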