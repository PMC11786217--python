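"""Inter-method agreement statistics.

Continuous agreement between size-measurement methods is summarised by the
Pearson correlation and Lin's concordance correlation coefficient (CCC,
which additionally penalises location and scale shift); pairs of dependent
non-overlapping correlations (e.g. diameter-vs-cube-root-volume for manual
versus automatic contours, measured on the same lesions) are compared with
the Pearson-Filon z test. Categorical agreement between response-assessment
methods is summarised by confusion matrices, percent agreement, Cohen's
kappa and the prevalence-and-bias-adjusted kappa (PABAK).

No multiple-testing correction is applied anywhere; all p-values are raw
and two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .response import Category, ResponseSequence

__all__ = [
    "ConfusionMatrix",
    "pearson_r",
    "lin_ccc",
    "percent_agreement",
    "cohen_kappa",
    "pabak",
    "pearson_filon_test",
    "confusion",
    "agreement_summary",
]

RESPONSE_LABELS = ("PD", "SD", "PR", "CR")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cross-tabulation of paired categorical assessments."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError("counts must be square and match the label list")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.labels)) != k:
            raise ValueError("labels must be unique")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], labels: Sequence[str] = RESPONSE_LABELS
    ) -> "ConfusionMatrix":
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for a, b in pairs:
            counts[idx[str(a)], idx[str(b)]] += 1
        return cls(tuple(labels), counts)


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two 1D vectors of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ``2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)`` with
    population (1/n) moments — Lin's original definition. Unlike Pearson's
    r, the CCC is 1 only for exact identity: any location or scale shift
    lowers it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two 1D vectors of equal length >= 3")
    vx, vy = x.var(), y.var()
    dmean = x.mean() - y.mean()
    denom = vx + vy + dmean**2
    if denom == 0:
        raise ValueError("CCC undefined: zero variances and equal means")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2 * sxy / denom)


def percent_agreement(cm: ConfusionMatrix) -> float:
    """Observed agreement: trace / n."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.n)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement from the marginals."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    p = cm.counts / cm.n
    po = np.trace(p)
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    if pe == 1:
        raise ValueError("kappa undefined: expected agreement is 1")
    return float((po - pe) / (1 - pe))


def pabak(cm: ConfusionMatrix) -> float:
    """Prevalence- and bias-adjusted kappa: (k p_o - 1) / (k - 1).

    Replaces the marginal-based chance term with the uniform k-category
    chance level 1/k, removing the sensitivity of Cohen's kappa to skewed
    prevalence.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    k = len(cm.labels)
    if k < 2:
        raise ValueError("PABAK needs >= 2 categories")
    po = percent_agreement(cm)
    return float((k * po - 1) / (k - 1))


def _pf_covariance(r12, r34, r13, r14, r23, r24) -> float:
    """Pearson-Filon asymptotic n*cov(r12, r34) for non-overlapping pairs."""
    return (
        0.5 * r12 * r34 * (r13**2 + r14**2 + r23**2 + r24**2)
        + r13 * r24
        + r14 * r23
        - (r12 * r13 * r14 + r12 * r23 * r24 + r34 * r13 * r23 + r34 * r14 * r24)
    )


def pearson_filon_test(x1, x2, x3, x4) -> tuple[float, float]:
    """Compare two dependent, non-overlapping correlations (Pearson-Filon).

    Tests r12 = corr(x1, x2) against r34 = corr(x3, x4) where all four
    variables are measured on the same n subjects. The z statistic is

        z = sqrt(n) (r12 - r34) / sqrt((1-r12^2)^2 + (1-r34^2)^2 - 2 k)

    with k the classical asymptotic covariance term assembled from the six
    pairwise correlations; the p-value is two-sided standard normal.
    Swapping the two pairs negates z. Identical pairs give z = 0, p = 1.
    """
    arrays = [np.asarray(v, dtype=float) for v in (x1, x2, x3, x4)]
    n = len(arrays[0])
    if any(a.shape != (n,) for a in arrays):
        raise ValueError("all four vectors must be 1D of equal length")
    if n < 10:
        raise ValueError("Pearson-Filon needs n >= 10")
    r = np.corrcoef(np.vstack(arrays))
    r12, r34 = r[0, 1], r[2, 3]
    if any(abs(v) >= 1 - 1e-12 for v in (r12, r34)):
        raise ValueError("degenerate correlation |r| = 1")
    if r12 == r34:
        return 0.0, 1.0
    k = _pf_covariance(r12, r34, r[0, 2], r[0, 3], r[1, 2], r[1, 3])
    denom = (1 - r12**2) ** 2 + (1 - r34**2) ** 2 - 2 * k
    if denom <= 0:
        raise ValueError("non-positive variance estimate; correlations too degenerate")
    z = np.sqrt(n) * (r12 - r34) / np.sqrt(denom)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def confusion(
    seqs_a: Iterable[ResponseSequence],
    seqs_b: Iterable[ResponseSequence],
    labels: Sequence[str] = RESPONSE_LABELS,
) -> ConfusionMatrix:
    """Cross-tabulate two methods' assessments over aligned follow-ups.

    Assessments are matched on (lesion, time) keys and only keys present in
    both methods enter — the paired-intersection handling used throughout
    the comparisons. Raises if the intersection is empty.
    """
    def keyed(seqs):
        out = {}
        for s in seqs:
            for t, c in zip(s.times, s.categories):
                out[(s.lesion_id, t)] = c.value if isinstance(c, Category) else str(c)
        return out

    a, b = keyed(seqs_a), keyed(seqs_b)
    common = sorted(set(a) & set(b))
    if not common:
        raise ValueError("no aligned (lesion, time) assessments between methods")
    return ConfusionMatrix.from_pairs(((a[k], b[k]) for k in common), labels)


def agreement_summary(cm: ConfusionMatrix) -> dict:
    """Percent agreement, kappa and PABAK for one method pair."""
    return {
        "n": cm.n,
        "percent_agreement": percent_agreement(cm),
        "kappa": cohen_kappa(cm),
        "pabak": pabak(cm),
    }
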