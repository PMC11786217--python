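"""One-year outcome and how early each assessment method detects it.

The 1-year response of a lesion is defined as the category of the first
follow-up after 365 days; lesions without such a follow-up are excluded.
For each assessment method the detection day is the day of the earliest
follow-up (within the window ending at that defining follow-up) whose
category already equals the final one — an earlier detection day means the
method anticipates the definitive outcome sooner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .response import Category, ResponseSequence
from .stability import paired_difference_test

ONE_YEAR_DAYS = 365.0  # "12 months"; the defining follow-up is the first with t > 365


class OneYearExclusion(ValueError):
    """Lesion has no follow-up beyond one year and is excluded."""


@dataclass(frozen=True)
class OutcomeRecord:
    lesion_id: str
    method: str
    final_category: Category
    detection_day: float
    followup_days: float


def _defining_index(times: tuple[float, ...]) -> int:
    for i, t in enumerate(times):
        if t > ONE_YEAR_DAYS:
            return i
    raise OneYearExclusion("no follow-up after one year")


def one_year_response(seq: ResponseSequence) -> Category:
    """Category of the first follow-up after 365 days (the final outcome)."""
    return seq.categories[_defining_index(seq.times)]


def time_to_outcome(seq: ResponseSequence, final_category: Category | str) -> float:
    """Day the final category is first observed.

    Searches follow-ups up to and including the defining one (the first
    after 365 days); the minimum possible value is the first follow-up day
    (the final response was visible immediately), the maximum is the
    defining follow-up's own day (it was never seen earlier).
    """
    final_category = Category(final_category)
    stop = _defining_index(seq.times)
    for t, c in zip(seq.times[: stop + 1], seq.categories[: stop + 1]):
        if c == final_category:
            return float(t)
    raise ValueError("final category never observed — inconsistent with its definition")


def outcome_record(seq: ResponseSequence) -> OutcomeRecord:
    final = one_year_response(seq)
    return OutcomeRecord(
        lesion_id=seq.lesion_id,
        method=seq.method,
        final_category=final,
        detection_day=time_to_outcome(seq, final),
        followup_days=float(seq.times[-1]),
    )


def cohort_outcome_summary(
    sequences_by_method: dict[str, list[ResponseSequence]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection-day summary per method, plus pairwise paired Wilcoxon tests.

    Each method's own 1-year response is used as its final outcome. Only
    lesions eligible in a given method (>= 1 follow-up after one year)
    contribute; pairwise tests are paired on the lesion intersection.
    Returns (per-method summary, pairwise p-value table).
    """
    records: dict[str, dict[str, OutcomeRecord]] = {}
    for method, seqs in sequences_by_method.items():
        per = {}
        for seq in seqs:
            try:
                per[seq.lesion_id] = outcome_record(seq)
            except OneYearExclusion:
                continue
        records[method] = per

    if not any(records.values()):
        raise ValueError("no lesion has a follow-up beyond one year")

    rows = []
    for method, per in records.items():
        days = np.array([r.detection_day for r in per.values()])
        if len(days) == 0:
            continue
        rows.append(
            {
                "method": method,
                "n_lesions": len(days),
                "mean_detection_day": days.mean(),
                "median_detection_day": float(np.median(days)),
                "sd_detection_day": days.std(ddof=1) if len(days) > 1 else 0.0,
            }
        )
    summary = pd.DataFrame(rows)

    methods = [m for m in records if len(records[m])]
    pvals = pd.DataFrame(np.nan, index=methods, columns=methods)
    for i, ma in enumerate(methods):
        for mb in methods[i + 1 :]:
            common = sorted(set(records[ma]) & set(records[mb]))
            if len(common) < 2:
                continue
            da = [records[ma][l].detection_day for l in common]
            db = [records[mb][l].detection_day for l in common]
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = paired_difference_test(da, db)
            pvals.loc[ma, mb] = pvals.loc[mb, ma] = p
    return summary, pvals
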