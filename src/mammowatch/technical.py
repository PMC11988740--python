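"""Technical monitoring: defect classification, monthly levels, trend, alerts.

A processed mammography study can exhibit one of two technical defects:

* **group A** — the model produced no output at all;
* **group B** — the model analyzed only one, two, or three of the four
  images comprising a standard study (CC and MLO views of each breast).

The monthly defect level per group is ``100 * D / S`` where ``D`` counts
that month's defective studies and ``S`` the studies submitted that month.
A least-squares trend line ``y = a x + b`` is fitted to the per-month
average of the two group levels, and an alert is raised for any month where
a group's level reaches the threshold (default 10%; the pass criterion is
strictly "less than", so the boundary alerts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_A",
    "GROUP_B",
    "NO_DEFECT",
    "classify_defect",
    "defect_level",
    "MonthlyDefectReport",
    "monthly_series",
    "average_levels",
    "TrendLine",
    "trend",
    "alert",
    "technical_report",
]

GROUP_A = "A"
GROUP_B = "B"
NO_DEFECT = "none"

DEFAULT_THRESHOLD = 10.0  # percent of the monthly study flow


def classify_defect(output_present: bool, n_images_analyzed: int) -> str:
    """Classify one study's defect group from its output state."""
    if not 0 <= n_images_analyzed <= 4:
        raise ValueError("n_images_analyzed must be between 0 and 4")
    if not output_present:
        return GROUP_A
    if 1 <= n_images_analyzed <= 3:
        return GROUP_B
    return NO_DEFECT


def defect_level(d: int, s: int) -> float:
    """Defect level in percent: 100 * D / S."""
    if s < 1:
        raise ValueError("S must be at least 1")
    if not 0 <= d <= s:
        raise ValueError("D must lie between 0 and S")
    return 100.0 * d / s


@dataclass(frozen=True)
class MonthlyDefectReport:
    """Defect accounting for one monitoring month."""

    month: int
    n_submitted: int
    n_group_a: int
    n_group_b: int
    level_a: float
    level_b: float

    @property
    def level_combined(self) -> float:
        return self.level_a + self.level_b

    @property
    def level_average(self) -> float:
        """Average of the two group levels (the trend-line response)."""
        return (self.level_a + self.level_b) / 2.0

    def as_dict(self) -> dict:
        return {
            "month": self.month,
            "n_submitted": self.n_submitted,
            "n_group_a": self.n_group_a,
            "n_group_b": self.n_group_b,
            "level_a": self.level_a,
            "level_b": self.level_b,
            "level_combined": self.level_combined,
        }


def monthly_series(studies: pd.DataFrame) -> list[MonthlyDefectReport]:
    """Per-month defect reports, ordered by month.

    Months with no submitted studies are absent from the series, not
    zero-filled: a level is only defined where there was a study flow.
    """
    if len(studies) == 0:
        raise ValueError("cannot monitor an empty study table")
    groups = [
        classify_defect(bool(o), int(k))
        for o, k in zip(studies["output_present"], studies["n_images_analyzed"])
    ]
    df = studies.assign(_group=groups)
    out = []
    for month, part in df.groupby("month", sort=True):
        s = len(part)
        d_a = int((part["_group"] == GROUP_A).sum())
        d_b = int((part["_group"] == GROUP_B).sum())
        out.append(
            MonthlyDefectReport(
                month=int(month),
                n_submitted=s,
                n_group_a=d_a,
                n_group_b=d_b,
                level_a=defect_level(d_a, s),
                level_b=defect_level(d_b, s),
            )
        )
    return out


def average_levels(series: list[MonthlyDefectReport]) -> dict[str, float]:
    """Arithmetic mean of the monthly levels across the monitoring window."""
    if not series:
        raise ValueError("empty monthly series")
    return {
        "level_a": float(np.mean([r.level_a for r in series])),
        "level_b": float(np.mean([r.level_b for r in series])),
        "level_combined": float(np.mean([r.level_combined for r in series])),
    }


@dataclass(frozen=True)
class TrendLine:
    """Least-squares line y = a x + b over (month, level) points."""

    slope: float
    intercept: float

    def predict(self, month: float) -> float:
        return self.slope * month + self.intercept

    def as_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept}


def trend(months, levels) -> TrendLine:
    """Ordinary least squares of defect level on month index."""
    months = np.asarray(months, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if months.size < 2 or np.unique(months).size < 2:
        raise ValueError("trend requires at least two distinct months")
    a, b = np.polyfit(months, levels, deg=1)
    return TrendLine(slope=float(a), intercept=float(b))


def alert(level: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Alert when a defect level reaches the threshold.

    The pass criterion is a level strictly below the threshold, so a level
    exactly at the threshold alerts.
    """
    if not 0.0 <= level <= 100.0:
        raise ValueError("level must lie in [0, 100]")
    return level >= threshold


def technical_report(
    studies: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> dict:
    """Full technical-monitoring summary as a JSON-safe document.

    Includes the per-month reports, window averages, the trend line on the
    per-month average level (plus per-group trends when the window spans at
    least two months), and the alert months per group.
    """
    series = monthly_series(studies)
    months = [r.month for r in series]
    doc: dict = {
        "threshold": threshold,
        "months": [r.as_dict() for r in series],
        "averages": average_levels(series),
        "alerts": {
            "group_a": [r.month for r in series if alert(r.level_a, threshold)],
            "group_b": [r.month for r in series if alert(r.level_b, threshold)],
        },
    }
    if len(set(months)) >= 2:
        doc["trend"] = {
            "average": trend(months, [r.level_average for r in series]).as_dict(),
            "group_a": trend(months, [r.level_a for r in series]).as_dict(),
            "group_b": trend(months, [r.level_b for r in series]).as_dict(),
        }
    else:
        doc["trend"] = None
    return doc
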