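"""End-user feedback aggregation and output-conformance checklists.

Radiologists using the AI in routine practice submit one of two responses
per study — "agree" or "disagree" with the AI outputs.  The aggregate
agree/disagree split is reported in percent with largest-remainder rounding
so the two displayed percentages always sum to exactly 100.0.

Separately, the AI's study outputs (additional image series, DICOM SR) are
checked against two versioned requirement checklists shipped as YAML data:

* the **functional** checklist — modality-independent output requirements
  (masks present, labeled and within the organ, uncropped images, model
  name/version and timestamp, a "For research purposes only" notification,
  no contradicting data, masks distinguishable on monochrome monitors);
* the **diagnostic** checklist — mammography-specific response capabilities
  (mass / calcification detection and classification, enlarged lymph-node
  detection, an ACR density category per breast, and a study-level
  malignancy probability).

Descriptors are declared, not parsed from DICOM; every flag is tri-state
(yes / no / unknown) and an unknown flag can never produce a "pass"
verdict — at best the overall verdict is "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AgreementSummary",
    "agreement_rate",
    "split_percentages",
    "OutputDescriptor",
    "Checklist",
    "load_checklist",
    "ConformanceReport",
    "evaluate_functional",
    "evaluate_diagnostic",
]

ALL_CAPABILITIES = frozenset(
    {
        "mass_detection",
        "calcification_detection",
        "lymph_node_detection",
        "density_category",
        "study_probability",
    }
)


def split_percentages(counts, decimals: int = 1) -> list[float]:
    """Percentages of total with largest-remainder rounding.

    The returned values sum to exactly 100 at the requested precision;
    leftover rounding units go to the largest fractional remainders
    (ties broken by position).
    """
    counts = [int(c) for c in counts]
    total = sum(counts)
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    units = 10 ** decimals
    raw = [100.0 * units * c / total for c in counts]
    floors = [int(np.floor(r)) for r in raw]
    leftover = 100 * units - sum(floors)
    order = sorted(range(len(counts)), key=lambda i: (-(raw[i] - floors[i]), i))
    for i in order[:leftover]:
        floors[i] += 1
    return [f / units for f in floors]


@dataclass(frozen=True)
class AgreementSummary:
    n: int
    n_agree: int
    n_disagree: int
    pct_agree: float
    pct_disagree: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "n_agree": self.n_agree,
            "n_disagree": self.n_disagree,
            "pct_agree": self.pct_agree,
            "pct_disagree": self.pct_disagree,
        }


def agreement_rate(records) -> AgreementSummary:
    """Aggregate agree/disagree feedback records.

    ``records`` is a DataFrame with a ``response`` column or any iterable of
    "agree"/"disagree" strings.  Percentages are reported to one decimal and
    reconciled to sum to 100.0.
    """
    if isinstance(records, pd.DataFrame):
        responses = records["response"].tolist()
    else:
        responses = list(records)
    if not responses:
        raise ValueError("cannot aggregate empty feedback")
    bad = set(responses) - {"agree", "disagree"}
    if bad:
        raise ValueError(f"invalid responses: {sorted(bad)}")
    n_agree = responses.count("agree")
    n_disagree = len(responses) - n_agree
    pct_agree, pct_disagree = split_percentages([n_agree, n_disagree], decimals=1)
    return AgreementSummary(
        n=len(responses),
        n_agree=n_agree,
        n_disagree=n_disagree,
        pct_agree=pct_agree,
        pct_disagree=pct_disagree,
    )


@dataclass(frozen=True)
class OutputDescriptor:
    """Declared properties of one AI study output.

    Boolean flags are tri-state: ``True`` / ``False`` / ``None`` (unknown).
    ``mask_rendering`` is "monochrome-compatible" or "color-only";
    ``finding_capabilities`` lists the supported diagnostic responses.
    """

    has_additional_series: bool | None = None
    masks_on_all_views: bool | None = None
    masks_within_organ: bool | None = None
    masks_labeled: bool | None = None
    images_uncropped: bool | None = None
    has_structured_report: bool | None = None
    has_name_and_version: bool | None = None
    has_timestamp: bool | None = None
    has_research_only_label: bool | None = None
    no_contradictions: bool | None = None
    mask_rendering: str | None = None
    finding_capabilities: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.mask_rendering not in (None, "monochrome-compatible", "color-only"):
            raise ValueError(
                "mask_rendering must be 'monochrome-compatible' or 'color-only'"
            )
        unknown = set(self.finding_capabilities) - ALL_CAPABILITIES
        if unknown:
            raise ValueError(f"unknown capabilities: {sorted(unknown)}")
        object.__setattr__(self, "finding_capabilities", frozenset(self.finding_capabilities))

    @classmethod
    def from_mapping(cls, mapping) -> "OutputDescriptor":
        kwargs = dict(mapping)
        caps = kwargs.pop("finding_capabilities", None) or []
        return cls(finding_capabilities=frozenset(caps), **kwargs)

    @classmethod
    def fully_conformant(cls) -> "OutputDescriptor":
        """A descriptor satisfying every checklist item (useful baseline)."""
        return cls(
            has_additional_series=True,
            masks_on_all_views=True,
            masks_within_organ=True,
            masks_labeled=True,
            images_uncropped=True,
            has_structured_report=True,
            has_name_and_version=True,
            has_timestamp=True,
            has_research_only_label=True,
            no_contradictions=True,
            mask_rendering="monochrome-compatible",
            finding_capabilities=ALL_CAPABILITIES,
        )


@dataclass(frozen=True)
class ChecklistItem:
    id: str
    text: str
    predicate: str


@dataclass(frozen=True)
class Checklist:
    id: str
    version: int
    title: str
    items: tuple[ChecklistItem, ...]


def load_checklist(name_or_path: str) -> Checklist:
    """Load a checklist manifest: "functional", "diagnostic", or a YAML path."""
    if name_or_path in ("functional", "diagnostic"):
        ref = resources.files("mammowatch.data") / f"checklist_{name_or_path}.yaml"
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        with open(name_or_path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return Checklist(
        id=raw["id"],
        version=int(raw["version"]),
        title=raw["title"],
        items=tuple(
            ChecklistItem(id=i["id"], text=i["text"], predicate=i["predicate"])
            for i in raw["items"]
        ),
    )


def _verdict(descriptor: OutputDescriptor, predicate: str) -> str:
    """Resolve one checklist predicate to pass / fail / unknown."""
    if predicate.startswith("flag:"):
        value = getattr(descriptor, predicate[5:])
        if value is None:
            return "unknown"
        return "pass" if value else "fail"
    if predicate == "monochrome_masks":
        if descriptor.mask_rendering is None:
            return "unknown"
        return "pass" if descriptor.mask_rendering == "monochrome-compatible" else "fail"
    if predicate.startswith("capability:"):
        return "pass" if predicate[11:] in descriptor.finding_capabilities else "fail"
    raise ValueError(f"unknown checklist predicate: {predicate}")


@dataclass(frozen=True)
class ConformanceReport:
    """Per-item verdicts against one checklist plus the overall verdict."""

    checklist_id: str
    checklist_version: int
    items: tuple[tuple[str, str], ...]  # (item id, verdict)
    overall: str  # pass | fail | unknown

    @property
    def passed(self) -> bool:
        return self.overall == "pass"

    def as_dict(self) -> dict:
        return {
            "checklist": self.checklist_id,
            "version": self.checklist_version,
            "items": {item_id: verdict for item_id, verdict in self.items},
            "overall": self.overall,
        }


def _evaluate(descriptor: OutputDescriptor, checklist: Checklist) -> ConformanceReport:
    verdicts = tuple(
        (item.id, _verdict(descriptor, item.predicate)) for item in checklist.items
    )
    values = [v for _, v in verdicts]
    if "fail" in values:
        overall = "fail"
    elif "unknown" in values:
        overall = "unknown"
    else:
        overall = "pass"
    return ConformanceReport(
        checklist_id=checklist.id,
        checklist_version=checklist.version,
        items=verdicts,
        overall=overall,
    )


def evaluate_functional(
    descriptor: OutputDescriptor, checklist: Checklist | None = None
) -> ConformanceReport:
    """Check a study output against the baseline functional requirements."""
    return _evaluate(descriptor, checklist or load_checklist("functional"))


def evaluate_diagnostic(
    descriptor: OutputDescriptor, checklist: Checklist | None = None
) -> ConformanceReport:
    """Check the declared capabilities against the diagnostic requirements."""
    return _evaluate(descriptor, checklist or load_checklist("diagnostic"))
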