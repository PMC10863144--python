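"""Actionable copy-number variant selection.

Biallelic deletions (CN = 0) of tumor suppressors and focal amplifications
(CN >= 10) of oncogenes are retained; calls classified benign/likely benign by
ACMG or failing manual IGV review are excluded.  One record is emitted per
qualifying (segment, gene) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .knowledge import KnowledgeBase

__all__ = ["CnvSegment", "SelectedCnv", "select_actionable_cnvs"]

logger = logging.getLogger(__name__)

ACMG_CLASSES = frozenset(
    {"benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic"}
)
_BENIGN = frozenset({"benign", "likely_benign"})


@dataclass
class CnvSegment:
    """A copy-number segment: 0-based half-open interval with integer CN."""

    chrom: str
    start: int
    end: int
    copy_number: float
    genes: tuple[str, ...] = ()
    acmg_class: str | None = None
    igv_flag: str = "not_reviewed"  # passed | failed | not_reviewed
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"CNV segment {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.copy_number < 0:
            raise ValueError(f"negative copy number {self.copy_number}")
        if self.acmg_class is not None and self.acmg_class not in ACMG_CLASSES:
            raise ValueError(f"unknown ACMG class {self.acmg_class!r}")
        if self.igv_flag not in {"passed", "failed", "not_reviewed"}:
            raise ValueError(f"unknown IGV flag {self.igv_flag!r}")
        self.genes = tuple(self.genes)


@dataclass
class SelectedCnv:
    """One actionable (segment, gene) pair."""

    segment: CnvSegment
    gene: str
    kind: str  # deletion | amplification
    dual_role: bool = field(default=False)  # gene role is "both"

    @property
    def sample_id(self) -> str:
        return self.segment.sample_id


def select_actionable_cnvs(
    segments: Iterable[CnvSegment],
    kb: KnowledgeBase,
    amp_cutoff: float = 10.0,
    respect_igv: bool = True,
) -> list[SelectedCnv]:
    """Select actionable CNVs.

    A (segment, gene) pair qualifies iff CN = 0 and the gene is a tumor
    suppressor (deletion), or CN >= ``amp_cutoff`` and the gene is an oncogene
    (amplification).  Genes with role ``both`` qualify under either branch and
    are flagged.  ACMG benign/likely-benign segments and (with ``respect_igv``)
    segments that failed IGV review are excluded; ``not_reviewed`` is treated
    as passed.  Segments overlapping no annotated gene are skipped with a
    logged notice.  Output is deduplicated by (segment position, gene) and
    independent of input ordering.
    """
    selected: dict[tuple[str, int, int, str, str], SelectedCnv] = {}
    for seg in segments:
        if not seg.genes:
            logger.info(
                "CNV segment %s:%d-%d overlaps no annotated gene; skipped",
                seg.chrom, seg.start, seg.end,
            )
            continue
        if seg.acmg_class in _BENIGN:
            continue
        if respect_igv and seg.igv_flag == "failed":
            continue
        for gene in dict.fromkeys(seg.genes):  # dedupe, keep order
            role = kb.role(gene)
            kind = None
            if seg.copy_number == 0 and role in {"tumor_suppressor", "both"}:
                kind = "deletion"
            elif seg.copy_number >= amp_cutoff and role in {"oncogene", "both"}:
                kind = "amplification"
            if kind is None:
                continue
            key = (seg.sample_id, seg.chrom, seg.start, seg.end, gene)
            selected.setdefault(
                key,
                SelectedCnv(segment=seg, gene=gene, kind=kind, dual_role=role == "both"),
            )
    return [selected[k] for k in sorted(selected)]
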