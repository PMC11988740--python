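"""Calibration testing: obtained metrics against developer-claimed metrics.

"Calibration testing" here is external validation of diagnostic accuracy on
a reference cohort, not probability calibration: the model's scores are
evaluated on an annotated calibration dataset and the resulting metric set
is compared with the metrics the developer claims for the model.

The verdict applies two criteria:

* the obtained AUC must meet a floor (default 0.81, matching the lower
  bound of a reference radiologist's AUC confidence interval);
* no claimed metric may be undercut by more than a maximum downward
  *relative* deviation (default 10% of the claimed value).  Upward
  deviations never violate, and metrics the developer did not claim are
  skipped.

The verdict uses unrounded deviations; rounding (half away from zero) is
applied for display only, so a -10.4% deviation printed as -10% still
fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .metrics import MetricSet, ROCCurve, round_half_away

__all__ = [
    "ClaimedMetrics",
    "CalibrationCriteria",
    "Violation",
    "CalibrationVerdict",
    "relative_difference",
    "evaluate",
    "calibration_report",
]

_METRIC_SLOTS = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")


@dataclass(frozen=True)
class ClaimedMetrics:
    """Developer-declared metric values; ``None`` means "not claimed" (NA)."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    auc: float | None = None

    def __post_init__(self) -> None:
        for name in _METRIC_SLOTS:
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"claimed {name} must lie in [0, 1]")

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in _METRIC_SLOTS}

    @classmethod
    def from_mapping(cls, mapping) -> "ClaimedMetrics":
        """Build from a parsed YAML/JSON mapping; "NA"/null mean not claimed."""
        kwargs = {}
        for name in _METRIC_SLOTS:
            v = mapping.get(name)
            if isinstance(v, str) and v.strip().upper() in {"NA", "N/A", ""}:
                v = None
            kwargs[name] = None if v is None else float(v)
        return cls(**kwargs)


@dataclass(frozen=True)
class CalibrationCriteria:
    """Pass criteria: AUC floor and maximum downward relative deviation (%)."""

    auc_min: float = 0.81
    max_downward_relative_deviation: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc_min <= 1.0:
            raise ValueError("auc_min must lie in [0, 1]")
        if self.max_downward_relative_deviation <= 0:
            raise ValueError("the deviation bound must be positive")


@dataclass(frozen=True)
class Violation:
    metric: str
    reason: str
    value: float

    def as_dict(self) -> dict:
        return {"metric": self.metric, "reason": self.reason, "value": self.value}


@dataclass(frozen=True)
class CalibrationVerdict:
    """Pass/fail decision with per-metric relative deviations (percent)."""

    passed: bool
    deviations: dict[str, float] = field(default_factory=dict)
    violations: tuple[Violation, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.violations) == 0):
            raise ValueError("passed must be true iff there are no violations")

    @property
    def recommendation(self) -> str:
        return "integrate" if self.passed else "update and repeat"


def relative_difference(claimed: float, obtained: float, decimals: int = 0) -> float:
    """Relative difference in percent: 100 * (obtained - claimed) / claimed.

    Rounded half away from zero to the requested decimals (table-display
    convention).  Undefined for a zero claim.
    """
    if claimed == 0:
        raise ValueError("relative difference is undefined for a zero claim")
    return round_half_away(100.0 * (obtained - claimed) / claimed, decimals)


def evaluate(
    obtained: MetricSet,
    claimed: ClaimedMetrics,
    criteria: CalibrationCriteria = CalibrationCriteria(),
) -> CalibrationVerdict:
    """Issue the calibration pass/fail verdict.

    Violations: an obtained AUC below the floor, and any claimed metric whose
    unrounded relative deviation is below minus the allowed bound.  Boundary
    values pass ("met or exceeded" the criteria).
    """
    if obtained.auc is None:
        raise ValueError("the obtained metric set must include AUC")

    violations: list[Violation] = []
    if obtained.auc < criteria.auc_min:
        violations.append(
            Violation(
                metric="auc",
                reason=f"AUC {obtained.auc:.3f} is below the required minimum "
                f"{criteria.auc_min}",
                value=obtained.auc,
            )
        )

    deviations: dict[str, float] = {}
    bound = criteria.max_downward_relative_deviation
    for name, claim in claimed.as_dict().items():
        if claim is None:
            continue
        value = getattr(obtained, name)
        if value is None:
            continue  # undefined obtained metrics are excluded from the check
        dev = 100.0 * (value - claim) / claim
        deviations[name] = dev
        if dev < -bound:
            violations.append(
                Violation(
                    metric=name,
                    reason=f"{name} deviates {dev:+.1f}% from the claimed "
                    f"{claim} (allowed: -{bound}%)",
                    value=dev,
                )
            )

    return CalibrationVerdict(
        passed=not violations,
        deviations=deviations,
        violations=tuple(violations),
    )


def calibration_report(
    verdict: CalibrationVerdict,
    obtained: MetricSet,
    claimed: ClaimedMetrics,
    criteria: CalibrationCriteria = CalibrationCriteria(),
    curve: ROCCurve | None = None,
    decimals: int = 0,
) -> dict:
    """Machine-readable calibration-testing report (JSON-safe).

    Echoes the inputs, the criteria, the per-metric deviations (both exact
    and display-rounded), the verdict with its violation list, and the ROC
    operating-point table when a curve is supplied.
    """
    doc = {
        "criteria": {
            "auc_min": criteria.auc_min,
            "max_downward_relative_deviation": criteria.max_downward_relative_deviation,
        },
        "claimed": claimed.as_dict(),
        "obtained": obtained.as_dict(),
        "obtained_rounded": obtained.rounded(2),
        "relative_differences": {
            name: round_half_away(dev, decimals)
            for name, dev in verdict.deviations.items()
        },
        "relative_differences_exact": dict(verdict.deviations),
        "passed": verdict.passed,
        "recommendation": verdict.recommendation,
        "violations": [v.as_dict() for v in verdict.violations],
    }
    if curve is not None:
        doc["roc_points"] = [
            {
                "fpr": fpr,
                "tpr": tpr,
                "threshold": None if thr == float("inf") else thr,
            }
            for fpr, tpr, thr in curve.points()
        ]
    return doc
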