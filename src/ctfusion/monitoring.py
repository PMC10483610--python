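"""Longitudinal interpretation of mutant-transcript levels in serial biopsies.

Mutant copies/uL from digital PCR across serial samples of one patient are
summarised as fold changes between consecutive timepoints and bucketed into
qualitative categories (increase / stable / marked_decrease /
not_detected_both). The default folds (>= 2x up, <= 0.2x down) separate the
canonical response patterns — rising levels under progression, stable
levels under disease stabilisation, a roughly five-fold drop under partial
response — but carry no validated clinical meaning: this module is
exploratory, and its outputs say so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "DEFAULT_UP_FOLD",
    "DEFAULT_DOWN_FOLD",
    "RESPONSE_EXPECTATION",
    "TimePoint",
    "TrendCall",
    "SeriesSummary",
    "classify_trend",
    "summarize_series",
]

DEFAULT_UP_FOLD = 2.0
DEFAULT_DOWN_FOLD = 0.2

#: expected trend category per clinical response label
#: (PD progressive disease, SD stable disease, PR partial response)
RESPONSE_EXPECTATION = {"PD": "increase", "SD": "stable", "PR": "marked_decrease"}


@dataclass(frozen=True)
class TimePoint:
    sample_id: str
    ordinal: float                      # date as an ordinal/day number
    copies_per_ul: float                # dPCR mutant concentration
    counts: int | None = None           # optional probe counts
    response: str = "unknown"           # PD | SD | PR | unknown

    def __post_init__(self) -> None:
        if self.copies_per_ul < 0:
            raise ValueError(f"{self.sample_id}: copies/uL must be >= 0")
        if self.response not in ("PD", "SD", "PR", "unknown"):
            raise ValueError(f"{self.sample_id}: unknown response label {self.response!r}")

    @property
    def detected(self) -> bool:
        return self.copies_per_ul > 0


@dataclass(frozen=True)
class TrendCall:
    fold_change: float | None   # follow-up / baseline; None when both undetected
    category: str               # increase | stable | marked_decrease | not_detected_both
    exploratory: bool = True


@dataclass
class SeriesSummary:
    patient_id: str
    trends: list[TrendCall]
    expected_categories: list[str | None]
    n_labelled: int
    n_matching: int
    label_concordance: float | None
    exploratory: bool = True


def classify_trend(
    baseline: TimePoint,
    followup: TimePoint,
    up_fold: float = DEFAULT_UP_FOLD,
    down_fold: float = DEFAULT_DOWN_FOLD,
) -> TrendCall:
    """Bucket the change between two timepoints.

    fold = follow-up / baseline. Category: ``increase`` when
    fold >= up_fold, ``marked_decrease`` when fold <= down_fold, else
    ``stable``. Zero handling: both undetected -> ``not_detected_both``;
    appearance from zero -> ``increase`` (fold inf); clearance to zero ->
    ``marked_decrease`` (fold 0, the strongest decrease signal).
    """
    if followup.ordinal <= baseline.ordinal:
        raise ValueError(
            f"follow-up {followup.sample_id} (t={followup.ordinal}) does not follow "
            f"baseline {baseline.sample_id} (t={baseline.ordinal})"
        )
    if up_fold <= 1.0 or not 0.0 <= down_fold < 1.0:
        raise ValueError("need up_fold > 1 and 0 <= down_fold < 1")
    if not baseline.detected and not followup.detected:
        return TrendCall(fold_change=None, category="not_detected_both")
    if not baseline.detected:
        return TrendCall(fold_change=math.inf, category="increase")
    fold = followup.copies_per_ul / baseline.copies_per_ul
    if fold >= up_fold:
        category = "increase"
    elif fold <= down_fold:
        category = "marked_decrease"
    else:
        category = "stable"
    return TrendCall(fold_change=fold, category=category)


def summarize_series(
    series: Sequence[TimePoint],
    patient_id: str = "",
    up_fold: float = DEFAULT_UP_FOLD,
    down_fold: float = DEFAULT_DOWN_FOLD,
) -> SeriesSummary:
    """One trend call per consecutive pair of timepoints, plus concordance
    with clinical response labels where present.

    The label of an interval is the follow-up timepoint's response; the
    expected category per label is :data:`RESPONSE_EXPECTATION`.
    """
    if len(series) < 2:
        raise ValueError("need >= 2 timepoints")
    ordinals = [tp.ordinal for tp in series]
    if any(b <= a for a, b in zip(ordinals, ordinals[1:])):
        raise ValueError(f"timepoints must be strictly ordered, got ordinals {ordinals}")
    trends: list[TrendCall] = []
    expected: list[str | None] = []
    for base, follow in zip(series, series[1:]):
        trends.append(classify_trend(base, follow, up_fold, down_fold))
        expected.append(RESPONSE_EXPECTATION.get(follow.response))
    labelled = [(t, e) for t, e in zip(trends, expected) if e is not None]
    n_match = sum(t.category == e for t, e in labelled)
    return SeriesSummary(
        patient_id=patient_id,
        trends=trends,
        expected_categories=expected,
        n_labelled=len(labelled),
        n_matching=n_match,
        label_concordance=(n_match / len(labelled)) if labelled else None,
    )
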