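"""Clinical monitoring: monthly expert review sampling and rubric scoring.

An expert radiologist reviews a random monthly sample of AI-processed
studies and assigns each one a category from a four-level rubric.  Each
category carries a fixed (localization, interpretation) score pair:

=====================  ============  ==============
category               localization  interpretation
=====================  ============  ==============
agreement                       1.0             1.0
incorrect_assessment            0.5             0.5
false_positive                 0.25            0.25
false_negative                  0.0             0.0
=====================  ============  ==============

The monthly clinical assessment score is 100 * (L + I) / 2 where L and I
are the arithmetic means of the two axes over the month's reviews.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RUBRIC_SCORES",
    "rubric_scores",
    "MonthSchedule",
    "DEFAULT_SCHEDULE",
    "monthly_sample",
    "ClinicalMonthReport",
    "clinical_score",
    "clinical_report",
]

RUBRIC_SCORES: dict[str, tuple[float, float]] = {
    "agreement": (1.0, 1.0),
    "incorrect_assessment": (0.5, 0.5),
    "false_positive": (0.25, 0.25),
    "false_negative": (0.0, 0.0),
}


def rubric_scores(category: str) -> tuple[float, float]:
    """(localization, interpretation) score pair for a rubric category."""
    try:
        return RUBRIC_SCORES[category]
    except KeyError:
        raise ValueError(
            f"unknown rubric category {category!r}; "
            f"expected one of {sorted(RUBRIC_SCORES)}"
        ) from None


@dataclass(frozen=True)
class MonthSchedule:
    """Monthly review sample sizes as (first_month, last_month, size) rules.

    The default mirrors a monitoring program that reviewed 20 studies per
    month for the first ten months and 80 per month for the following
    twelve — 1160 reviews over 22 months.
    """

    rules: tuple[tuple[int, int, int], ...] = ((1, 10, 20), (11, 22, 80))

    def size_for(self, month: int) -> int:
        for first, last, size in self.rules:
            if first <= month <= last:
                return size
        raise ValueError(f"month {month} is outside the review schedule")

    @property
    def months(self) -> list[int]:
        out: list[int] = []
        for first, last, _ in self.rules:
            out.extend(range(first, last + 1))
        return out

    def total(self) -> int:
        return sum(self.size_for(m) for m in self.months)


DEFAULT_SCHEDULE = MonthSchedule()


def monthly_sample(
    eligible_ids,
    month: int,
    seed: int,
    schedule: MonthSchedule = DEFAULT_SCHEDULE,
) -> list:
    """Simple random sample (without replacement) of the month's review set.

    The sample size comes from the schedule; the draw is reproducible given
    the seed and month (each month uses an independent substream).
    """
    eligible = list(eligible_ids)
    size = schedule.size_for(month)
    if len(eligible) < size:
        raise ValueError(
            f"month {month} schedules {size} reviews but only "
            f"{len(eligible)} studies are eligible"
        )
    rng = np.random.default_rng([int(seed), int(month)])
    picked = rng.choice(len(eligible), size=size, replace=False)
    return [eligible[i] for i in picked]


@dataclass(frozen=True)
class ClinicalMonthReport:
    """One month's aggregated clinical assessment."""

    month: int
    n_reviewed: int
    mean_localization: float
    mean_interpretation: float
    score: float  # percent in [0, 100]: 100 * (L + I) / 2

    def as_dict(self) -> dict:
        return {
            "month": self.month,
            "n_reviewed": self.n_reviewed,
            "mean_localization": self.mean_localization,
            "mean_interpretation": self.mean_interpretation,
            "score": self.score,
        }


def clinical_score(reviews: pd.DataFrame, month: int | None = None) -> ClinicalMonthReport:
    """Aggregate one month's reviews into the clinical assessment score.

    L and I are arithmetic means of the localization and interpretation
    scores; the clinical assessment score is 100 * (L + I) / 2.  Reviews
    missing explicit score columns fall back to the rubric pair for their
    category.
    """
    if len(reviews) == 0:
        raise ValueError("cannot score an empty review set")
    if "localization" in reviews.columns and "interpretation" in reviews.columns:
        loc = reviews["localization"].to_numpy(dtype=float)
        interp = reviews["interpretation"].to_numpy(dtype=float)
    else:
        pairs = [rubric_scores(c) for c in reviews["category"]]
        loc = np.array([p[0] for p in pairs])
        interp = np.array([p[1] for p in pairs])
    mean_l = float(np.mean(loc))
    mean_i = float(np.mean(interp))
    if month is None:
        month = int(reviews["month"].iloc[0]) if "month" in reviews.columns else 0
    return ClinicalMonthReport(
        month=month,
        n_reviewed=len(reviews),
        mean_localization=mean_l,
        mean_interpretation=mean_i,
        score=100.0 * (mean_l + mean_i) / 2.0,
    )


def clinical_report(reviews: pd.DataFrame) -> list[ClinicalMonthReport]:
    """Per-month clinical assessment reports, ordered by month."""
    if len(reviews) == 0:
        raise ValueError("cannot report on an empty review table")
    return [
        clinical_score(part, month=int(month))
        for month, part in reviews.groupby("month", sort=True)
    ]
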