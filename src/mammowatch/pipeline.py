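"""Lifecycle orchestration: simulate -> calibrate -> monitor -> feedback.

The lifecycle mirrors how an external evaluation program runs a diagnostic
AI model through its stages: the model is first validated on a calibration
cohort against the developer's claimed metrics; if it passes, it enters
prospective monitoring where technical defects and clinical review scores
are tracked monthly, and end-user feedback is aggregated.  A calibration
failure carries the recommendation "update and repeat"; monitoring then
only proceeds when the force flag is set.

All randomness is derived from a single root seed via
:class:`numpy.random.SeedSequence` stream splitting, so two runs with equal
configuration produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import (
    CalibrationCriteria,
    ClaimedMetrics,
    calibration_report,
    evaluate,
)
from .clinical import DEFAULT_SCHEDULE, MonthSchedule, clinical_report, monthly_sample
from .feedback import agreement_rate
from .io import write_feedback, write_reviews, write_studies
from .metrics import evaluate_scores
from .simulate import (
    SimulationConfig,
    separation_for_auc,
    simulate_feedback,
    simulate_monitoring_cohort,
    simulate_reviews,
    simulate_scores,
)
from .technical import technical_report

__all__ = ["LifecycleConfig", "run_lifecycle", "render_report"]


@dataclass(frozen=True)
class LifecycleConfig:
    """Full configuration of one lifecycle run.

    Defaults describe a mature model under surveillance: a 100-study 50/50
    calibration cohort simulated at theoretical AUC 0.91 and checked against
    claimed metrics of 0.82/0.82/0.82 (accuracy/sensitivity/specificity) and
    a claimed AUC of 0.89; a 22-month monitoring window whose combined
    defect rate declines linearly from 9% to 1% (group B dominant); the
    20-then-80 monthly clinical review schedule; and a feedback stream with
    a 79.2% agreement probability.
    """

    seed: int = 0
    # calibration cohort
    calibration_n_pos: int = 50
    calibration_n_neg: int = 50
    calibration_auc: float = 0.91
    claimed: ClaimedMetrics = field(
        default_factory=lambda: ClaimedMetrics(
            accuracy=0.82, sensitivity=0.82, specificity=0.82, auc=0.89
        )
    )
    criteria: CalibrationCriteria = field(default_factory=CalibrationCriteria)
    # prospective monitoring cohort
    n_months: int = 22
    studies_per_month: int = 200
    prevalence: float = 0.10
    defect_rate_a_initial: float = 0.014
    defect_rate_b_initial: float = 0.076
    defect_rate_a_final: float = 0.002
    defect_rate_b_final: float = 0.008
    defect_threshold: float = 10.0
    # clinical review
    schedule: MonthSchedule = field(default_factory=lambda: DEFAULT_SCHEDULE)
    p_incorrect: float = 0.25
    # end-user feedback
    n_feedback: int = 8406
    p_agree: float = 0.792
    # proceed to monitoring even when calibration fails
    force: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if self.studies_per_month < 1 or self.n_months < 1:
            raise ValueError("monitoring window must be non-empty")

    def calibration_sim(self) -> SimulationConfig:
        return SimulationConfig(
            n_pos=self.calibration_n_pos,
            n_neg=self.calibration_n_neg,
            mu_pos=separation_for_auc(self.calibration_auc),
            mu_neg=0.0,
            sigma=1.0,
            seed=self.seed,
        )

    def monitoring_sim(self) -> SimulationConfig:
        n_total = self.studies_per_month * self.n_months
        n_pos = int(round(self.prevalence * n_total))
        return SimulationConfig(
            n_pos=n_pos,
            n_neg=n_total - n_pos,
            mu_pos=separation_for_auc(self.calibration_auc),
            mu_neg=0.0,
            sigma=1.0,
            rate_no_output=self.defect_rate_a_initial,
            rate_partial=self.defect_rate_b_initial,
            rate_no_output_final=self.defect_rate_a_final,
            rate_partial_final=self.defect_rate_b_final,
            n_months=self.n_months,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "calibration": {
                "n_pos": self.calibration_n_pos,
                "n_neg": self.calibration_n_neg,
                "theoretical_auc": self.calibration_auc,
                "claimed": self.claimed.as_dict(),
                "criteria": {
                    "auc_min": self.criteria.auc_min,
                    "max_downward_relative_deviation": self.criteria.max_downward_relative_deviation,
                },
            },
            "monitoring": {
                "n_months": self.n_months,
                "studies_per_month": self.studies_per_month,
                "prevalence": self.prevalence,
                "defect_rate_a": [self.defect_rate_a_initial, self.defect_rate_a_final],
                "defect_rate_b": [self.defect_rate_b_initial, self.defect_rate_b_final],
                "defect_threshold": self.defect_threshold,
            },
            "clinical": {
                "schedule": [list(rule) for rule in self.schedule.rules],
                "p_incorrect": self.p_incorrect,
            },
            "feedback": {"n": self.n_feedback, "p_agree": self.p_agree},
            "force": self.force,
        }

    @classmethod
    def from_mapping(cls, raw: dict) -> "LifecycleConfig":
        """Build from a parsed YAML/JSON document (the to_dict layout)."""
        cal = raw.get("calibration", {})
        mon = raw.get("monitoring", {})
        cli = raw.get("clinical", {})
        fb = raw.get("feedback", {})
        kwargs: dict = {"seed": int(raw.get("seed", 0)), "force": bool(raw.get("force", False))}
        if "n_pos" in cal:
            kwargs["calibration_n_pos"] = int(cal["n_pos"])
        if "n_neg" in cal:
            kwargs["calibration_n_neg"] = int(cal["n_neg"])
        if "theoretical_auc" in cal:
            kwargs["calibration_auc"] = float(cal["theoretical_auc"])
        if "claimed" in cal:
            kwargs["claimed"] = ClaimedMetrics.from_mapping(cal["claimed"])
        if "criteria" in cal:
            kwargs["criteria"] = CalibrationCriteria(
                auc_min=float(cal["criteria"].get("auc_min", 0.81)),
                max_downward_relative_deviation=float(
                    cal["criteria"].get("max_downward_relative_deviation", 10.0)
                ),
            )
        for src, dst, cast in (
            ("n_months", "n_months", int),
            ("studies_per_month", "studies_per_month", int),
            ("prevalence", "prevalence", float),
            ("defect_threshold", "defect_threshold", float),
        ):
            if src in mon:
                kwargs[dst] = cast(mon[src])
        if "defect_rate_a" in mon:
            kwargs["defect_rate_a_initial"], kwargs["defect_rate_a_final"] = (
                float(mon["defect_rate_a"][0]),
                float(mon["defect_rate_a"][1]),
            )
        if "defect_rate_b" in mon:
            kwargs["defect_rate_b_initial"], kwargs["defect_rate_b_final"] = (
                float(mon["defect_rate_b"][0]),
                float(mon["defect_rate_b"][1]),
            )
        if "schedule" in cli:
            kwargs["schedule"] = MonthSchedule(
                rules=tuple(tuple(int(x) for x in rule) for rule in cli["schedule"])
            )
        if "p_incorrect" in cli:
            kwargs["p_incorrect"] = float(cli["p_incorrect"])
        if "n" in fb:
            kwargs["n_feedback"] = int(fb["n"])
        if "p_agree" in fb:
            kwargs["p_agree"] = float(fb["p_agree"])
        return cls(**kwargs)


def _jsonify(obj):
    """Recursively convert numpy scalars/arrays so json can serialize."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _config_hash(config: LifecycleConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def run_lifecycle(config: LifecycleConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full lifecycle and return the consolidated report.

    Stages run in order: calibration testing, technical monitoring, clinical
    monitoring, feedback aggregation.  When calibration fails and ``force``
    is not set, the monitoring stages are marked "not run".  With ``outdir``
    given, the stage tables (studies, reviews, feedback) and the report JSON
    are written there.
    """
    root = np.random.SeedSequence(config.seed)
    rng_cal, rng_mon, rng_rev, rng_fb = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    report: dict = {
        "provenance": {
            "tool": "mammowatch",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": _config_hash(config),
            "config": config.to_dict(),
        },
        "stages": {},
    }

    # --- calibration testing ------------------------------------------------
    cal_studies = simulate_scores(config.calibration_sim(), id_prefix="cal", rng=rng_cal)
    evaluation = evaluate_scores(
        cal_studies["study_score"].to_numpy(), cal_studies["true_label"].to_numpy()
    )
    verdict = evaluate(evaluation.metrics, config.claimed, config.criteria)
    cal_doc = calibration_report(
        verdict, evaluation.metrics, config.claimed, config.criteria, curve=evaluation.curve
    )
    cal_doc.update(
        {
            "status": "run",
            "n_studies": len(cal_studies),
            "threshold": evaluation.threshold,
            "youden_j": evaluation.youden_j,
        }
    )
    report["stages"]["calibration"] = cal_doc

    run_monitoring = verdict.passed or config.force
    mon_studies = reviews = fb = None

    if run_monitoring:
        # --- technical monitoring -------------------------------------------
        mon_studies = simulate_monitoring_cohort(config.monitoring_sim(), rng=rng_mon)
        tech_doc = technical_report(mon_studies, threshold=config.defect_threshold)
        tech_doc["status"] = "run"
        report["stages"]["technical_monitoring"] = tech_doc

        # --- clinical monitoring --------------------------------------------
        processed = mon_studies[mon_studies["output_present"]]
        monthly_reports = []
        review_parts = []
        schedule_months = set(config.schedule.months)
        for month, part in processed.groupby("month", sort=True):
            if int(month) not in schedule_months:
                continue
            sampled_ids = monthly_sample(
                part["study_id"].tolist(), int(month), config.seed, config.schedule
            )
            sample = part[part["study_id"].isin(sampled_ids)]
            calls = sample["study_score"].to_numpy() >= evaluation.threshold
            review_parts.append(
                simulate_reviews(sample, calls, config.p_incorrect, rng_rev)
            )
        if review_parts:
            import pandas as pd

            reviews = pd.concat(review_parts, ignore_index=True)
            monthly_reports = clinical_report(reviews)
        report["stages"]["clinical_monitoring"] = {
            "status": "run",
            "n_reviews": 0 if reviews is None else len(reviews),
            "months": [r.as_dict() for r in monthly_reports],
        }

        # --- end-user feedback ----------------------------------------------
        fb = simulate_feedback(config.n_feedback, config.p_agree, rng_fb)
        report["stages"]["feedback"] = {"status": "run", **agreement_rate(fb).as_dict()}
    else:
        for stage in ("technical_monitoring", "clinical_monitoring", "feedback"):
            report["stages"][stage] = {"status": "not run"}

    # --- consolidated verdicts ---------------------------------------------
    clinical_months = report["stages"]["clinical_monitoring"].get("months", [])
    report["verdicts"] = {
        "calibration_passed": verdict.passed,
        "recommendation": verdict.recommendation,
        "alert_months": report["stages"]["technical_monitoring"].get("alerts"),
        "monthly_clinical_scores": {
            str(m["month"]): m["score"] for m in clinical_months
        },
        "agreement_pct": report["stages"]["feedback"].get("pct_agree"),
    }

    report = _jsonify(report)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_studies(cal_studies, outdir / "calibration_studies.csv")
        if mon_studies is not None:
            write_studies(mon_studies, outdir / "studies.csv")
        if reviews is not None:
            write_reviews(reviews, outdir / "reviews.csv")
        if fb is not None:
            write_feedback(fb, outdir / "feedback.csv")
        (outdir / "lifecycle.json").write_text(render_report(report), encoding="utf-8")

    return report


def render_report(report: dict, format: str = "json") -> str:
    """Render a lifecycle report as canonical JSON or a plain-text summary."""
    if format == "json":
        return json.dumps(report, indent=2, sort_keys=True) + "\n"
    if format != "text":
        raise ValueError(f"unsupported format: {format!r}")

    lines = [
        f"mammowatch lifecycle report (seed {report['provenance']['seed']}, "
        f"version {report['provenance']['version']})",
        "",
    ]
    cal = report["stages"]["calibration"]
    lines.append(
        f"calibration: {'PASS' if cal['passed'] else 'FAIL'} "
        f"(AUC {cal['obtained']['auc']:.3f}, threshold {cal['threshold']:.3f}); "
        f"recommendation: {cal['recommendation']}"
    )
    for v in cal["violations"]:
        lines.append(f"  violation: {v['reason']}")
    tech = report["stages"]["technical_monitoring"]
    if tech["status"] == "run":
        avg = tech["averages"]
        alerts = tech["alerts"]
        lines.append(
            f"technical monitoring: avg level A {avg['level_a']:.2f}%, "
            f"B {avg['level_b']:.2f}%; alert months A={alerts['group_a']} "
            f"B={alerts['group_b']}"
        )
        if tech["trend"]:
            t = tech["trend"]["average"]
            lines.append(
                f"  trend (average level): y = {t['slope']:.3f} x + {t['intercept']:.3f}"
            )
    else:
        lines.append("technical monitoring: not run")
    clin = report["stages"]["clinical_monitoring"]
    if clin["status"] == "run" and clin["months"]:
        first, last = clin["months"][0], clin["months"][-1]
        lines.append(
            f"clinical monitoring: {clin['n_reviews']} reviews; score "
            f"month {first['month']}: {first['score']:.1f} -> "
            f"month {last['month']}: {last['score']:.1f}"
        )
    else:
        lines.append("clinical monitoring: not run")
    fb = report["stages"]["feedback"]
    if fb["status"] == "run":
        lines.append(
            f"feedback: {fb['n']} responses, {fb['pct_agree']}% agree / "
            f"{fb['pct_disagree']}% disagree"
        )
    else:
        lines.append("feedback: not run")
    return "\n".join(lines) + "\n"
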