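"""Somatic, germline and tumor-only filtration cascades for annotated small variants.

Each cascade evaluates an ordered list of predicates per variant and returns the
kept set together with a :class:`FilterAudit` that attributes every removal to
the first failing rule.  Rule order affects only the audit, never membership:
the kept set is always the intersection of the single-rule kept sets.

Thresholds follow clinical-panel practice for relapsed neuroblastoma cohorts:
common polymorphisms above 1% population frequency are removed, calls need at
least 8 alternate-supporting reads and a variant allele frequency of at least
5%, and pathogenicity prioritization keeps variants with CADD (phred) strictly
above 20 or a CancerVar score strictly above 0.80.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

__all__ = [
    "CONSEQUENCES",
    "CLINVAR_CLASSES",
    "SmallVariant",
    "FilterAudit",
    "VariantInputError",
    "filter_somatic",
    "prioritize_pathogenic",
    "filter_tumor_only",
    "filter_germline",
]

CONSEQUENCES = frozenset(
    {
        "missense",
        "synonymous",
        "stopgain",
        "frameshift",
        "inframe_indel",
        "splice",
        "other_exonic",
        "non_exonic",
    }
)

CLINVAR_CLASSES = frozenset(
    {
        "Pathogenic",
        "Likely_pathogenic",
        "Benign",
        "Likely_benign",
        "VUS",
        "Conflicting",
    }
)

_PATHOGENIC = frozenset({"Pathogenic", "Likely_pathogenic"})


class VariantInputError(ValueError):
    """A variant record is missing mandatory fields or is internally inconsistent."""


@dataclass
class SmallVariant:
    """One annotated SNV/INDEL call.

    Positions are 1-based (VCF convention).  ``popmax_af`` is the maximum
    allele frequency over whatever reference population panels annotated the
    call; ``None`` means the variant was never observed, which passes rarity
    filters.  ``effect`` records the functional direction of the alteration
    (loss- vs gain-of-function) used for drug mechanism-concordance checks.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    sample_id: str = ""
    gene: str = ""
    consequence: str = "other_exonic"
    caller_pass: bool = True
    popmax_af: float | None = None
    cadd_phred: float | None = None
    cancervar_score: float | None = None
    clinvar_class: str | None = None
    intervar_class: str | None = None
    in_cosmic: bool = False
    alt_reads: int = 0
    depth: int = 1
    in_segdup: bool = False
    on_target: bool = True
    effect: str = "unknown"  # LOF | GOF | unknown

    def __post_init__(self) -> None:
        if not self.chrom or self.pos is None or not self.ref or not self.alt:
            raise VariantInputError(
                f"variant record missing mandatory field (chrom/pos/ref/alt): "
                f"{self.chrom!r}:{self.pos!r} {self.ref!r}>{self.alt!r}"
            )
        if self.vaf is None or not 0.0 <= self.vaf <= 1.0:
            raise VariantInputError(
                f"variant {self.key} has invalid VAF {self.vaf!r} (need 0..1)"
            )
        if self.consequence not in CONSEQUENCES:
            raise VariantInputError(
                f"variant {self.key} has unknown consequence {self.consequence!r}"
            )
        if self.alt_reads < 0 or self.depth <= 0:
            raise VariantInputError(
                f"variant {self.key} has invalid read support "
                f"(alt_reads={self.alt_reads}, depth={self.depth})"
            )
        if self.alt_reads > self.depth:
            raise VariantInputError(
                f"variant {self.key}: alt_reads {self.alt_reads} exceeds depth {self.depth}"
            )
        if self.alt_reads > 0 and abs(self.vaf - self.alt_reads / self.depth) > 0.01:
            raise VariantInputError(
                f"variant {self.key}: vaf {self.vaf:.4f} inconsistent with "
                f"{self.alt_reads}/{self.depth} reads"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity: (chrom, 1-based pos, ref, alt). All matching uses this."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterAudit:
    """Per-rule removal bookkeeping with first-failing-rule attribution."""

    input_count: int = 0
    kept_count: int = 0
    removed_by_rule: "OrderedDict[str, int]" = field(default_factory=OrderedDict)

    def check(self) -> None:
        total = self.kept_count + sum(self.removed_by_rule.values())
        if total != self.input_count:
            raise AssertionError(
                f"audit does not conserve records: kept {self.kept_count} + removed "
                f"{sum(self.removed_by_rule.values())} != input {self.input_count}"
            )


Rule = tuple[str, Callable[[SmallVariant], bool]]


def _run_cascade(
    variants: Iterable[SmallVariant], rules: Sequence[Rule]
) -> tuple[list[SmallVariant], FilterAudit]:
    """Apply rules in order; a variant is kept iff it passes every rule."""
    audit = FilterAudit(removed_by_rule=OrderedDict((name, 0) for name, _ in rules))
    kept: list[SmallVariant] = []
    for v in variants:
        audit.input_count += 1
        for name, passes in rules:
            if not passes(v):
                audit.removed_by_rule[name] += 1
                break
        else:
            kept.append(v)
    audit.kept_count = len(kept)
    audit.check()
    return kept, audit


def _somatic_rules(
    maf_cutoff: float, min_alt_reads: int, min_vaf: float
) -> list[Rule]:
    return [
        ("caller_fail", lambda v: v.caller_pass),
        ("segdup", lambda v: not v.in_segdup),
        (
            "common_polymorphism",
            lambda v: v.popmax_af is None or v.popmax_af <= maf_cutoff,
        ),
        ("off_target", lambda v: v.on_target),
        ("synonymous", lambda v: v.consequence != "synonymous"),
        ("read_support", lambda v: v.alt_reads >= min_alt_reads),
        ("low_vaf", lambda v: v.vaf >= min_vaf),
    ]


def filter_somatic(
    variants: Iterable[SmallVariant],
    maf_cutoff: float = 0.01,
    min_alt_reads: int = 8,
    min_vaf: float = 0.05,
) -> tuple[list[SmallVariant], FilterAudit]:
    """Somatic cascade: caller PASS, not segdup, rare (popmax <= ``maf_cutoff``),
    on-target, non-synonymous, >= ``min_alt_reads`` alternate reads,
    VAF >= ``min_vaf``.

    The MAF cutoff is strict (popmax exactly at the cutoff is kept).  The two
    read-support requirements are independent: failing either excludes.
    """
    return _run_cascade(variants, _somatic_rules(maf_cutoff, min_alt_reads, min_vaf))


def prioritize_pathogenic(
    variants: Iterable[SmallVariant],
    cadd_cutoff: float = 20.0,
    cancervar_cutoff: float = 0.80,
) -> list[SmallVariant]:
    """Pathogenicity prioritization of somatically filtered variants.

    Retained iff CADD phred is strictly above ``cadd_cutoff`` OR CancerVar is
    strictly above ``cancervar_cutoff``; an absent score fails its clause.
    """
    return [
        v
        for v in variants
        if (v.cadd_phred is not None and v.cadd_phred > cadd_cutoff)
        or (v.cancervar_score is not None and v.cancervar_score > cancervar_cutoff)
    ]


def filter_tumor_only(
    variants: Iterable[SmallVariant],
    popmax_cutoff: float = 0.001,
    cosmic_rescue: bool = True,
    maf_cutoff: float = 0.01,
    min_alt_reads: int = 8,
    min_vaf: float = 0.05,
) -> tuple[list[SmallVariant], FilterAudit]:
    """Tumor-only cascade for samples without a matched normal.

    All somatic rules apply first; then the stricter rarity rule removes a
    variant whose population maximum allele frequency exceeds ``popmax_cutoff``
    unless it is a known somatic (COSMIC) variant.  ``cosmic_rescue=False``
    switches to the strict reading where COSMIC membership does not rescue.
    """

    def rare_or_cosmic(v: SmallVariant) -> bool:
        rare = v.popmax_af is None or v.popmax_af <= popmax_cutoff
        if cosmic_rescue:
            return rare or v.in_cosmic
        return rare

    rules = _somatic_rules(maf_cutoff, min_alt_reads, min_vaf)
    rules.append(("tumor_only_popmax", rare_or_cosmic))
    return _run_cascade(variants, rules)


def filter_germline(
    variants: Iterable[SmallVariant],
    predisposition_genes: Iterable[str],
    maf_cutoff: float = 0.01,
) -> tuple[list[SmallVariant], FilterAudit]:
    """Germline cascade: restrict to cancer predisposition genes, then keep
    variants Pathogenic/Likely_pathogenic in ClinVar or InterVar, excluding
    ClinVar conflicting interpretations.

    Shared quality prefilters (caller PASS, segdup, rarity, on-target) apply
    first; synonymous and read-support rules are somatic-specific and do not.
    """
    gene_set = frozenset(predisposition_genes)
    if not gene_set:
        raise ValueError("predisposition gene list must be non-empty")
    rules: list[Rule] = [
        ("caller_fail", lambda v: v.caller_pass),
        ("segdup", lambda v: not v.in_segdup),
        (
            "common_polymorphism",
            lambda v: v.popmax_af is None or v.popmax_af <= maf_cutoff,
        ),
        ("off_target", lambda v: v.on_target),
        ("not_predisposition_gene", lambda v: v.gene in gene_set),
        ("clinvar_conflicting", lambda v: v.clinvar_class != "Conflicting"),
        (
            "not_pathogenic",
            lambda v: (v.clinvar_class in _PATHOGENIC)
            or (v.intervar_class in _PATHOGENIC),
        ),
    ]
    return _run_cascade(variants, rules)
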