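"""Stability of size measurements and response assessments.

Two perturbations are quantified:

* **rotation** — the lesion contour is rigidly rotated over a set of small
  angles (by default -20..20 deg in 2-deg steps about the x-axis, 21
  contours including the unrotated one) emulating variation in patient head
  positioning, and the coefficient of variation (CoV) of the re-measured
  size is computed across the set. Volumes enter as cube roots so the CoV
  is comparable with the (unidimensional) diameters. A rotation should not
  change a lesion's size, so a larger CoV means a less stable measurement
  method.
* **time** — a standard post-treatment size evolution is hypothesised to be
  monotone; the absolute Spearman correlation between time since treatment
  and size measures how monotone a measured trajectory is, and the rate of
  category changes between consecutive follow-up assessments measures
  response-label churn.

Paired method comparisons use a two-sided Wilcoxon signed-rank test on CoV
(or correlation) differences and a two-sided McNemar test on paired
response-change indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .mask_ops import (
    Mask3D,
    RotationSpec,
    cube_root_size,
    longest_axial_diameter,
    rotate_mask,
    volume_mm3,
)
from .response import Category, RanoThresholds, ResponseSequence, SizeSeries, classify_rano

__all__ = [
    "StabilityRecord",
    "rotated_sizes",
    "rotation_cov",
    "rotation_response_change",
    "temporal_monotonicity",
    "consecutive_change_count",
    "pooled_change_rate",
    "paired_difference_test",
    "unpaired_difference_test",
    "paired_rate_test",
]

# exact-vs-approximate switchover sample sizes for the paired tests
WILCOXON_EXACT_MAX_N = 25
MCNEMAR_EXACT_MAX_DISCORDANT = 25


@dataclass(frozen=True)
class StabilityRecord:
    """Per lesion x method stability summary."""

    lesion_id: str
    method: str
    cov_rotation: float | None = None
    any_response_change_rotation: bool | None = None
    abs_spearman_time: float | None = None
    n_consecutive_changes: int | None = None
    n_consecutive_pairs: int | None = None

    def __post_init__(self) -> None:
        if self.cov_rotation is not None and self.cov_rotation < 0:
            raise ValueError("cov must be >= 0")
        if self.abs_spearman_time is not None and not 0 <= self.abs_spearman_time <= 1 + 1e-12:
            raise ValueError("abs Spearman must lie in [0, 1]")
        if (
            self.n_consecutive_changes is not None
            and self.n_consecutive_pairs is not None
            and self.n_consecutive_changes > self.n_consecutive_pairs
        ):
            raise ValueError("changes cannot exceed pairs")


def _measure(mask: Mask3D, method: str) -> float:
    """Size on the common mm scale: diameter, or cube-root volume."""
    if method == "diameter":
        return longest_axial_diameter(mask)
    if method == "volume":
        return cube_root_size(volume_mm3(mask))
    raise ValueError(f"method must be 'diameter' or 'volume', got {method!r}")


def rotated_sizes(mask: Mask3D, method: str, spec: RotationSpec) -> np.ndarray:
    """Re-measured size (mm scale) for every rotation in the spec."""
    return np.array(
        [_measure(rotate_mask(mask, a, spec.axes), method) for a in spec.angles]
    )


def rotation_cov(mask: Mask3D, method: str, spec: RotationSpec) -> float:
    """Coefficient of variation of the size across the rotation set.

    CoV = sample sd (n-1 denominator) / mean over the rotated
    re-measurements; volumes are cube-rooted before entering, so diameter
    and volume CoVs are directly comparable.
    """
    sizes = rotated_sizes(mask, method, spec)
    mean = sizes.mean()
    if mean == 0:
        raise ValueError("degenerate mask: mean rotated size is 0")
    return float(sizes.std(ddof=1) / mean)


def rotation_response_change(
    series: SizeSeries,
    last_mask: Mask3D,
    spec: RotationSpec,
    thresholds: RanoThresholds,
    method: str,
) -> bool:
    """Does any rotation of the last time point change its RANO category?

    Only the final contour is rotated; baseline and nadir stay unrotated.
    Each rotated re-measurement replaces the final size in the series and
    the lesion is re-classified; the reference category is the one obtained
    at angle 0 (the unrotated mask). ``method`` must match the series units:
    "diameter" re-measures the longest axial diameter (mm), "volume" the
    voxel volume (mm^3).
    """
    if series.n_followups < 1:
        raise ValueError("series needs at least one follow-up")
    if not any(a == 0 for a in spec.angles):
        raise ValueError("rotation spec must include angle 0 (reference)")

    def final_category(size: float) -> Category:
        values = series.values[:-1] + (size,)
        reseries = SizeSeries(series.lesion_id, series.method, series.times, values)
        return classify_rano(reseries, thresholds).categories[-1]

    if method == "diameter":
        sizes = [longest_axial_diameter(rotate_mask(last_mask, a, spec.axes)) for a in spec.angles]
    elif method == "volume":
        sizes = [volume_mm3(rotate_mask(last_mask, a, spec.axes)) for a in spec.angles]
    else:
        raise ValueError(f"method must be 'diameter' or 'volume', got {method!r}")
    ref = final_category(float(sizes[list(spec.angles).index(0)]))
    return any(final_category(float(s)) != ref for s in sizes)


def temporal_monotonicity(series: SizeSeries | None = None, *, times=None, values=None) -> float:
    """Absolute Spearman correlation between time since treatment and size.

    Requires at least 3 time points. A perfectly monotone trajectory gives
    1; a constant series carries no evidence of a monotone trend and is
    defined as 0 (with a warning). Ties are handled by average ranks.
    """
    if series is not None:
        times, values = series.times, series.values
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 3:
        raise ValueError("temporal monotonicity needs >= 3 time points")
    if np.ptp(values) == 0:
        warnings.warn("constant size series: monotonicity defined as 0", stacklevel=2)
        return 0.0
    rho = stats.spearmanr(times, values).statistic
    return float(abs(rho))


def consecutive_change_count(categories: Sequence) -> tuple[int, int]:
    """Count category changes between consecutive assessments.

    Returns ``(changes, pairs)`` with ``pairs = len - 1``: the sequence
    [PR, CR, CR] has 1 change out of 2 pairs and [PR, PR, PD, PR] has 2 out
    of 3. Depends only on the equality pattern, not the labels themselves.
    """
    if isinstance(categories, ResponseSequence):
        categories = categories.categories
    if len(categories) < 2:
        raise ValueError("need at least 2 assessed categories")
    changes = sum(a != b for a, b in zip(categories, categories[1:]))
    return int(changes), len(categories) - 1


def pooled_change_rate(records: Iterable[tuple[int, int] | StabilityRecord]) -> float:
    """Overall change rate pooled across lesions: sum(changes)/sum(pairs).

    Pooling accumulates all occurrences before dividing — it is not the
    mean of per-lesion rates.
    """
    changes = pairs = 0
    for rec in records:
        if isinstance(rec, StabilityRecord):
            c, p = rec.n_consecutive_changes, rec.n_consecutive_pairs
        else:
            c, p = rec
        changes += c
        pairs += p
    if pairs == 0:
        raise ValueError("no consecutive pairs to pool")
    return changes / pairs


def paired_difference_test(values_a, values_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired measurements.

    Zero differences are discarded; the exact null distribution is used for
    up to 25 informative untied pairs, the normal approximation (with
    continuity correction) otherwise. All-zero differences give p = 1 with
    a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1D of equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= WILCOXON_EXACT_MAX_N and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue)


def unpaired_difference_test(values_a, values_b) -> float:
    """Two-sided Mann-Whitney rank-sum p-value for independent samples."""
    return float(stats.mannwhitneyu(values_a, values_b, alternative="two-sided").pvalue)


def paired_rate_test(flags_a, flags_b) -> float:
    """Two-sided McNemar p-value comparing two paired boolean outcomes.

    Built from the discordant counts of the 2x2 contingency table: exact
    binomial when fewer than 25 discordant pairs, chi-squared with
    continuity correction otherwise. No discordant pairs give p = 1.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired flag vectors must be 1D of equal length")
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n_disc = n10 + n01
    if n_disc == 0:
        return 1.0
    if n_disc < MCNEMAR_EXACT_MAX_DISCORDANT:
        return float(stats.binomtest(n10, n_disc, 0.5).pvalue)
    stat = (abs(n10 - n01) - 1) ** 2 / n_disc
    return float(stats.chi2.sf(stat, df=1))
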