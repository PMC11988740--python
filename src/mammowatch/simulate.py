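"""Synthetic study cohorts with known ground truth for lifecycle testing.

Every downstream stage — calibration testing, technical and clinical
monitoring, feedback aggregation — is exercised on simulated cohorts whose
true operating characteristics are controlled:

* **Scores** follow an equal-variance binormal latent model: a study with
  pathology draws a latent value from N(mu_pos, sigma), one without from
  N(mu_neg, sigma), and the latent value is mapped to a probability by the
  logistic function.  AUC is invariant under any strictly increasing
  transform, so the theoretical AUC is the closed form
  Phi((mu_pos - mu_neg) / (sigma * sqrt(2))).
* **Technical defects** are injected per study as one of two kinds: group A
  (the model produced no output at all) or group B (the model analyzed only
  1-3 of the four standard views, CC and MLO per breast).  Group A takes
  precedence when a study is drawn into both.
* **Expert reviews** assign each studied output one rubric category driven by
  its confusion cell: concordant calls are "agreement", false positives and
  false negatives map to their categories, and a configurable fraction of
  true positives is downgraded to "incorrect assessment" (not all lesions
  marked).
* **Feedback** is a Bernoulli agree/disagree stream from a pool of end users.

All randomness flows through :func:`numpy.random.default_rng`; identical
configuration and seed reproduce byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import norm

from .clinical import RUBRIC_SCORES

__all__ = [
    "SimulationConfig",
    "STUDY_COLUMNS",
    "theoretical_auc",
    "separation_for_auc",
    "simulate_scores",
    "inject_defects",
    "simulate_reviews",
    "simulate_feedback",
    "simulate_monitoring_cohort",
]

#: Column contract of studies tables (studies.csv).
STUDY_COLUMNS = [
    "study_id",
    "month",
    "score_left",
    "score_right",
    "study_score",
    "n_images_analyzed",
    "output_present",
    "true_label",
    "birads",
]

# BI-RADS composition conditional on class, from the prospective-stream
# mix of a large urban screening program (1-2 benign, 3-5 suspicious,
# 6 biopsy-proven).
_BIRADS_NEG = np.array([1, 2])
_BIRADS_NEG_P = np.array([118672, 383053], dtype=float)
_BIRADS_POS = np.array([3, 4, 5, 6])
_BIRADS_POS_P = np.array([37268, 13273, 1771, 1013], dtype=float)
_BIRADS_NEG_P /= _BIRADS_NEG_P.sum()
_BIRADS_POS_P /= _BIRADS_POS_P.sum()


def theoretical_auc(mu_pos: float, mu_neg: float, sigma: float) -> float:
    """Closed-form AUC of the equal-variance binormal model."""
    return float(norm.cdf((mu_pos - mu_neg) / (sigma * np.sqrt(2.0))))


def separation_for_auc(auc: float, sigma: float = 1.0) -> float:
    """Latent mean separation mu_pos - mu_neg that yields a target AUC."""
    if not 0.0 < auc < 1.0:
        raise ValueError("target AUC must lie strictly in (0, 1)")
    return float(ndtri(auc) * sigma * np.sqrt(2.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults describe a calibration-style cohort: 100 studies at 50/50 class
    balance, with latent separation tuned so the theoretical AUC is 0.91.
    ``rate_no_output`` / ``rate_partial`` are the month-1 probabilities of a
    group A / group B technical defect; when the ``*_final`` rates are set,
    per-month rates interpolate linearly across ``n_months`` (emulating a
    model whose stability improves over the monitoring window).
    """

    n_pos: int = 50
    n_neg: int = 50
    mu_pos: float = 1.896
    mu_neg: float = 0.0
    sigma: float = 1.0
    rate_no_output: float = 0.0
    rate_partial: float = 0.0
    p_agree: float = 0.792
    seed: int = 0
    n_months: int = 1
    rate_no_output_final: float | None = None
    rate_partial_final: float | None = None

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class counts must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_months < 1:
            raise ValueError("n_months must be at least 1")
        for name in ("rate_no_output", "rate_partial", "p_agree"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rate_no_output + self.rate_partial > 1.0:
            raise ValueError("defect rates must sum to at most 1")
        for name in ("rate_no_output_final", "rate_partial_final"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def theoretical_auc(self) -> float:
        return theoretical_auc(self.mu_pos, self.mu_neg, self.sigma)

    def rates_for_month(self, month: int) -> tuple[float, float]:
        """Defect rates in a given month under the linear decline schedule."""
        if self.n_months == 1:
            return self.rate_no_output, self.rate_partial
        t = (month - 1) / (self.n_months - 1)
        ra_final = self.rate_no_output_final
        rp_final = self.rate_partial_final
        ra = self.rate_no_output if ra_final is None else (1 - t) * self.rate_no_output + t * ra_final
        rp = self.rate_partial if rp_final is None else (1 - t) * self.rate_partial + t * rp_final
        return ra, rp


def simulate_scores(
    config: SimulationConfig, *, id_prefix: str = "study", rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw a scored cohort of ``n_pos + n_neg`` studies.

    Each study gets a latent binormal draw mapped through the logistic
    function; that value is the study-level score and is carried by the
    affected breast (chosen at random), while the contralateral breast gets
    an independent uniform score below it, so ``study_score`` equals
    ``max(score_left, score_right)`` by construction.  Months are assigned
    cyclically over ``n_months`` after shuffling, keeping the monthly flow
    balanced.  No defects are injected here (all four views analyzed).
    """
    n = config.n_pos + config.n_neg
    if n < 1:
        raise ValueError("cohort must contain at least one study")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    labels = np.zeros(n, dtype=int)
    labels[: config.n_pos] = 1
    rng.shuffle(labels)

    mu = np.where(labels == 1, config.mu_pos, config.mu_neg)
    latent = rng.normal(mu, config.sigma)
    study_score = expit(latent)

    affected_left = rng.random(n) < 0.5
    other = study_score * rng.random(n)
    score_left = np.where(affected_left, study_score, other)
    score_right = np.where(affected_left, other, study_score)

    birads = np.empty(n, dtype=int)
    pos = labels == 1
    birads[pos] = rng.choice(_BIRADS_POS, size=int(pos.sum()), p=_BIRADS_POS_P)
    birads[~pos] = rng.choice(_BIRADS_NEG, size=int((~pos).sum()), p=_BIRADS_NEG_P)

    month = 1 + np.arange(n) % config.n_months

    return pd.DataFrame(
        {
            "study_id": [f"{id_prefix}-{i:06d}" for i in range(n)],
            "month": month,
            "score_left": score_left,
            "score_right": score_right,
            "study_score": study_score,
            "n_images_analyzed": np.full(n, 4),
            "output_present": np.ones(n, dtype=bool),
            "true_label": labels,
            "birads": birads,
        }
    )


def inject_defects(
    studies: pd.DataFrame,
    rate_no_output: float,
    rate_partial: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Assign technical-defect state to each study independently.

    With probability ``rate_no_output`` a study becomes group A (no output:
    scores dropped, zero images analyzed); otherwise with probability
    ``rate_partial`` it becomes group B (1-3 of the four views analyzed,
    uniformly).  The two rates must sum to at most 1; group A takes
    precedence, as "no output" subsumes "partial output".
    """
    for name, v in (("rate_no_output", rate_no_output), ("rate_partial", rate_partial)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if rate_no_output + rate_partial > 1.0:
        raise ValueError("defect rates must sum to at most 1")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = studies.copy()
    n = len(out)
    u = rng.random(n)
    group_a = u < rate_no_output
    group_b = ~group_a & (u < rate_no_output + rate_partial)

    n_images = np.full(n, 4)
    n_images[group_b] = rng.integers(1, 4, size=int(group_b.sum()))
    n_images[group_a] = 0

    out["n_images_analyzed"] = n_images
    out["output_present"] = ~group_a
    # a study without output carries no scores
    for col in ("score_left", "score_right", "study_score"):
        out.loc[group_a, col] = np.nan
    return out


def simulate_reviews(
    studies: pd.DataFrame,
    calls,
    p_incorrect: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Assign one expert rubric category per study from its confusion cell.

    ``calls`` are the model's binary pathology calls aligned with ``studies``
    rows.  Concordant calls are "agreement"; discordant calls map to
    "false_positive" / "false_negative"; a true positive is downgraded to
    "incorrect_assessment" (only some lesions marked) with probability
    ``p_incorrect``.  Localization and interpretation scores are the fixed
    rubric pair for the category.
    """
    if not 0.0 <= p_incorrect <= 1.0:
        raise ValueError("p_incorrect must lie in [0, 1]")
    calls = np.asarray(calls, dtype=bool)
    if calls.shape[0] != len(studies):
        raise ValueError("calls must align with the studies rows")
    labels = studies["true_label"].to_numpy()
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("every study needs a binary true label")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = labels == 1
    downgrade = rng.random(len(studies)) < p_incorrect

    category = np.where(
        calls & truth,
        np.where(downgrade, "incorrect_assessment", "agreement"),
        np.where(~calls & ~truth, "agreement",
                 np.where(calls & ~truth, "false_positive", "false_negative")),
    )
    loc = np.array([RUBRIC_SCORES[c][0] for c in category])
    interp = np.array([RUBRIC_SCORES[c][1] for c in category])
    return pd.DataFrame(
        {
            "study_id": studies["study_id"].to_numpy(),
            "month": studies["month"].to_numpy(),
            "category": category,
            "localization": loc,
            "interpretation": interp,
        }
    )


def simulate_feedback(
    n: int,
    p_agree: float,
    seed: int | np.random.Generator = 0,
    n_users: int = 33,
) -> pd.DataFrame:
    """Draw ``n`` Bernoulli agree/disagree feedback records.

    Each record is attributed to one of ``n_users`` end users uniformly at
    random; the response is "agree" with probability ``p_agree``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= p_agree <= 1.0:
        raise ValueError("p_agree must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    agree = rng.random(n) < p_agree
    users = rng.integers(n_users, size=n)
    return pd.DataFrame(
        {
            "user_id": [f"user-{u:02d}" for u in users],
            "study_id": [f"fb-{i:06d}" for i in range(n)],
            "response": np.where(agree, "agree", "disagree"),
        }
    )


def simulate_monitoring_cohort(
    config: SimulationConfig,
    *,
    id_prefix: str = "mon",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Scored multi-month cohort with per-month defect injection.

    Draws the full cohort once, then injects defects month by month using
    :meth:`SimulationConfig.rates_for_month`, so a linear defect-rate decline
    across the monitoring window is reflected in the monthly defect levels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    studies = simulate_scores(config, id_prefix=id_prefix, rng=rng)
    parts = []
    for month, part in studies.groupby("month", sort=True):
        ra, rp = config.rates_for_month(int(month))
        parts.append(inject_defects(part, ra, rp, rng))
    return pd.concat(parts, ignore_index=True)
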