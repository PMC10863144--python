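"""Actionability tiering of molecular alterations.

Candidate alterations (filtered/prioritized SNV-INDELs, selected CNVs,
over-expression outliers, hypermutation and MSI-high calls) are matched to
knowledge-base drug records, pruned by mechanism concordance, and graded:

* ``VERY_HIGH`` — alteration validated to be directly targetable by an
  approved drug or an investigational agent (evidence ``validated_direct``);
* ``HIGH`` — novel alteration predicted pathogenic in a targetable gene or
  pathway (evidence ``pathway_predicted``).

Mechanism concordance: inhibitor/antagonist drug records are discordant with
loss-of-function alterations of tumor suppressors (an inhibitor cannot target
a lost function) and are dropped; gain-of-function alterations of oncogenes
retain them.  Alterations of unknown functional direction keep their records
but are never graded VERY_HIGH on mechanism grounds alone.  A candidate with
no surviving drug record is excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .knowledge import KnowledgeBase

__all__ = [
    "EVENT_CLASSES",
    "AlterationCandidate",
    "ActionableEvent",
    "CohortSummary",
    "classify_events",
    "summarize_cohort",
    "apportion_percentages",
    "percent_half_up",
    "truncated_percent",
]

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("SNV_INDEL", "CNV", "OVEREXPRESSION", "HYPERMUTATION", "MSI_HIGH")
_BURDEN_CLASSES = frozenset({"HYPERMUTATION", "MSI_HIGH"})
_DISCORDANT_MECHANISMS = frozenset({"inhibitor", "antagonist"})


@dataclass
class AlterationCandidate:
    """A pre-grading alteration candidate.

    ``effect`` is LOF/GOF/unknown; burden-class candidates (hypermutation,
    MSI-high) carry no gene.  ``detail`` holds class-specific payload (VAF,
    copy number, Z-score, TMB) for downstream tracking.
    """

    patient_id: str
    sample_id: str
    event_class: str
    gene: str | None = None
    effect: str = "unknown"
    provenance: str = ""
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.event_class not in _BURDEN_CLASSES and not self.gene:
            raise ValueError(f"{self.event_class} candidate requires a gene")


@dataclass
class ActionableEvent:
    patient_id: str
    sample_id: str
    event_class: str
    gene: str | None
    pathway: str
    priority: str  # VERY_HIGH | HIGH
    drugs: pd.DataFrame
    provenance: str = ""
    detail: dict = field(default_factory=dict)


def _prune_discordant(drugs: pd.DataFrame, effect: str, is_tsg: bool) -> pd.DataFrame:
    if effect == "LOF" and is_tsg:
        drugs = drugs[~drugs["mechanism"].isin(_DISCORDANT_MECHANISMS)]
    return drugs.reset_index(drop=True)


def classify_events(
    candidates: Iterable[AlterationCandidate], kb: KnowledgeBase
) -> list[ActionableEvent]:
    """Grade candidates into actionable events; see module docstring for rules."""
    events: list[ActionableEvent] = []
    for c in candidates:
        if c.event_class in _BURDEN_CLASSES:
            drugs = kb.checkpoint_drugs()
            events.append(
                ActionableEvent(
                    patient_id=c.patient_id,
                    sample_id=c.sample_id,
                    event_class=c.event_class,
                    gene=None,
                    pathway="immune checkpoint",
                    priority="VERY_HIGH",
                    drugs=drugs,
                    provenance=c.provenance,
                    detail=dict(c.detail),
                )
            )
            continue
        if not kb.has_gene(c.gene):
            logger.info("candidate gene %s absent from knowledge base; dropped", c.gene)
            continue
        drugs = _prune_discordant(
            kb.drugs_for(c.gene), c.effect, kb.is_tumor_suppressor(c.gene)
        )
        if drugs.empty:
            continue
        validated = (drugs["evidence"] == "validated_direct").any()
        if validated and c.effect != "unknown":
            priority = "VERY_HIGH"
        else:
            priority = "HIGH"
        events.append(
            ActionableEvent(
                patient_id=c.patient_id,
                sample_id=c.sample_id,
                event_class=c.event_class,
                gene=c.gene,
                pathway=kb.pathway(c.gene),
                priority=priority,
                drugs=drugs,
                provenance=c.provenance,
                detail=dict(c.detail),
            )
        )
    return events


# -- rounding helpers --------------------------------------------------------


def percent_half_up(numerator: float, denominator: float) -> int:
    """Integer percentage with ties rounded away from zero (half-up)."""
    if denominator == 0:
        return 0
    x = 100.0 * numerator / denominator
    return int(x + 0.5)


def truncated_percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage truncated (not rounded) to ``decimals`` places, e.g. 2/17 -> 11.7."""
    if denominator == 0:
        return 0.0
    scale = 10**decimals
    return int(100.0 * numerator / denominator * scale) / scale


def apportion_percentages(counts: Sequence[int]) -> list[int]:
    """Integer percentages of a composition that sum to exactly 100.

    Largest-remainder apportionment: floor each share, then hand the leftover
    points to the largest fractional remainders, breaking ties toward the
    larger count (then earlier position).  Reproduces the printed style of
    clinical summaries, e.g. (21, 8, 10, 1) -> (53, 20, 25, 2).
    """
    total = sum(counts)
    if total == 0:
        return [0] * len(counts)
    raw = [100.0 * c / total for c in counts]
    floors = [int(x) for x in raw]
    leftover = 100 - sum(floors)
    order = sorted(
        range(len(counts)),
        key=lambda i: (-(raw[i] - floors[i]), -counts[i], i),
    )
    out = list(floors)
    for i in order[:leftover]:
        out[i] += 1
    return out


# -- cohort summary ----------------------------------------------------------


@dataclass
class CohortSummary:
    """Event-class tallies and the gene/class-by-sample summary matrix."""

    matrix: pd.DataFrame  # rows: gene or burden class; cols: samples
    class_counts: dict[str, int]
    class_percent: dict[str, int]
    priority_counts: dict[str, int]
    n_samples: int
    n_samples_with_event: int
    percent_samples_with_event: int
    n_samples_very_high: int
    percent_samples_very_high: int


def summarize_cohort(
    events: Sequence[ActionableEvent], samples: Sequence[str]
) -> CohortSummary:
    """Cohort-level summary: per-class counts/percentages (summing to 100),
    priority counts, and the fraction of samples carrying >= 1 event."""
    samples = list(samples)
    rows = sorted(
        {e.gene if e.gene else e.event_class for e in events}
    )
    matrix = pd.DataFrame("", index=rows, columns=samples, dtype=object)
    for e in events:
        row = e.gene if e.gene else e.event_class
        cell = f"{e.event_class}:{e.priority}"
        prev = matrix.at[row, e.sample_id]
        matrix.at[row, e.sample_id] = f"{prev};{cell}" if prev else cell

    classes_present = [c for c in EVENT_CLASSES if any(e.event_class == c for e in events)]
    class_counts = {c: sum(e.event_class == c for e in events) for c in classes_present}
    pct = apportion_percentages(list(class_counts.values()))
    class_percent = dict(zip(class_counts, pct))

    priority_counts = {
        p: sum(e.priority == p for e in events) for p in ("VERY_HIGH", "HIGH")
    }
    with_event = {e.sample_id for e in events}
    very_high = {e.sample_id for e in events if e.priority == "VERY_HIGH"}
    return CohortSummary(
        matrix=matrix,
        class_counts=class_counts,
        class_percent=class_percent,
        priority_counts=priority_counts,
        n_samples=len(samples),
        n_samples_with_event=len(with_event),
        percent_samples_with_event=percent_half_up(len(with_event), len(samples))
        if samples
        else 0,
        n_samples_very_high=len(very_high),
        percent_samples_very_high=percent_half_up(len(very_high), len(samples))
        if samples
        else 0,
    )
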