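"""Readers and writers for the formats the pipeline touches, plus configuration.

Conventions: variant positions are 1-based (VCF/TSV); BED intervals are
0-based half-open.  The conversion lives in one routine
(:func:`position_overlaps_bed`).  Variants and CNVs are strandless genomic
events; expression is gene-symbol keyed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
import yaml

from .cnv_selection import CnvSegment
from .variant_filters import SmallVariant, VariantInputError

__all__ = [
    "VARIANT_COLUMNS",
    "PipelineConfig",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_bed",
    "write_bed",
    "position_overlaps_bed",
    "annotate_regions",
    "read_cnvs_tsv",
    "write_cnvs_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
]

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample_id", "gene", "consequence",
    "caller_pass", "popmax_af", "cadd_phred", "cancervar_score",
    "clinvar_class", "intervar_class", "in_cosmic", "alt_reads", "depth",
    "vaf", "in_segdup", "on_target", "effect",
]

_OPTIONAL_FLOATS = {"popmax_af", "cadd_phred", "cancervar_score"}
_OPTIONAL_STRS = {"clinvar_class", "intervar_class"}
_BOOLS = {"caller_pass", "in_cosmic", "in_segdup", "on_target"}


# -- variant TSV ---------------------------------------------------------------


def write_variants_tsv(variants: Iterable[SmallVariant], path: str | Path) -> None:
    rows = []
    for v in variants:
        row = {c: getattr(v, c) for c in VARIANT_COLUMNS}
        rows.append(row)
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[SmallVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = {"chrom", "pos", "ref", "alt", "vaf"}
    missing = mandatory - set(df.columns)
    if missing:
        raise VariantInputError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    out: list[SmallVariant] = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # 1-based + header
        kwargs: dict = {}
        for col in VARIANT_COLUMNS:
            raw = row.get(col, "")
            if raw == "" or raw == "None":
                continue
            try:
                if col == "pos":
                    kwargs[col] = int(raw)
                elif col in {"alt_reads", "depth"}:
                    kwargs[col] = int(float(raw))
                elif col == "vaf" or col in _OPTIONAL_FLOATS:
                    kwargs[col] = float(raw)
                elif col in _BOOLS:
                    kwargs[col] = raw in {"True", "true", "1"}
                else:
                    kwargs[col] = raw
            except ValueError as exc:
                raise VariantInputError(f"{path} line {i}: bad value {raw!r} for {col}") from exc
        try:
            out.append(SmallVariant(**kwargs))
        except (TypeError, VariantInputError) as exc:
            raise VariantInputError(f"{path} line {i}: {exc}") from exc
    return out


# -- variant VCF ---------------------------------------------------------------

_INFO_FIELDS = [
    ("GENE", "1", "String", "Gene symbol"),
    ("CSQ", "1", "String", "Consequence"),
    ("POPMAX_AF", "1", "Float", "Max population allele frequency"),
    ("CADD", "1", "Float", "CADD phred score"),
    ("CANCERVAR", "1", "Float", "CancerVar score"),
    ("CLNSIG", "1", "String", "ClinVar class"),
    ("INTERVAR", "1", "String", "InterVar class"),
    ("COSMIC", "0", "Flag", "In COSMIC"),
    ("VAF", "1", "Float", "Variant allele frequency"),
    ("ALT_READS", "1", "Integer", "Alt-supporting reads"),
    ("DP", "1", "Integer", "Depth"),
    ("SEGDUP", "0", "Flag", "In segmental duplication"),
    ("OFF_TARGET", "0", "Flag", "Outside target regions"),
    ("EFFECT", "1", "String", "LOF/GOF/unknown"),
]


def write_variants_vcf(
    variants: Sequence[SmallVariant], path: str | Path, contig_length: int = 250_000_000
) -> None:
    """Sites-only VCF 4.2 with the pipeline's annotation INFO keys."""
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=caller_fail,Description="Failed upstream caller filters">')
    for cid in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(cid, length=contig_length)
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt),
                filter="PASS" if v.caller_pass else "caller_fail",
            )
            rec.info["GENE"] = v.gene or "."
            rec.info["CSQ"] = v.consequence
            if v.popmax_af is not None:
                rec.info["POPMAX_AF"] = v.popmax_af
            if v.cadd_phred is not None:
                rec.info["CADD"] = v.cadd_phred
            if v.cancervar_score is not None:
                rec.info["CANCERVAR"] = v.cancervar_score
            if v.clinvar_class is not None:
                rec.info["CLNSIG"] = v.clinvar_class
            if v.intervar_class is not None:
                rec.info["INTERVAR"] = v.intervar_class
            if v.in_cosmic:
                rec.info["COSMIC"] = True
            rec.info["VAF"] = v.vaf
            rec.info["ALT_READS"] = v.alt_reads
            rec.info["DP"] = v.depth
            if v.in_segdup:
                rec.info["SEGDUP"] = True
            if not v.on_target:
                rec.info["OFF_TARGET"] = True
            rec.info["EFFECT"] = v.effect
            vcf.write(rec)


def read_variants_vcf(path: str | Path, sample_id: str = "") -> list[SmallVariant]:
    out: list[SmallVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            caller_pass = (not list(rec.filter)) or "PASS" in rec.filter
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                raise VariantInputError(f"{path}: record at {rec.contig}:{rec.pos} has no ALT")
            out.append(
                SmallVariant(
                    chrom=rec.contig, pos=rec.pos, ref=rec.ref, alt=alt,
                    vaf=float(info["VAF"]), sample_id=sample_id,
                    gene=str(info.get("GENE", "")).replace(".", ""),
                    consequence=str(info.get("CSQ", "other_exonic")),
                    caller_pass=caller_pass,
                    popmax_af=float(info["POPMAX_AF"]) if "POPMAX_AF" in info else None,
                    cadd_phred=float(info["CADD"]) if "CADD" in info else None,
                    cancervar_score=float(info["CANCERVAR"]) if "CANCERVAR" in info else None,
                    clinvar_class=str(info["CLNSIG"]) if "CLNSIG" in info else None,
                    intervar_class=str(info["INTERVAR"]) if "INTERVAR" in info else None,
                    in_cosmic=bool(info.get("COSMIC", False)),
                    alt_reads=int(info.get("ALT_READS", 0)),
                    depth=int(info.get("DP", 1)),
                    in_segdup=bool(info.get("SEGDUP", False)),
                    on_target=not bool(info.get("OFF_TARGET", False)),
                    effect=str(info.get("EFFECT", "unknown")),
                )
            )
    return out


# -- BED -----------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def position_overlaps_bed(
    chrom: str, pos: int, ref: str, intervals: Sequence[tuple[str, int, int]]
) -> bool:
    """Overlap of a 1-based variant against 0-based half-open BED intervals.

    An INDEL overlaps if any affected reference base does: the variant spans
    0-based positions [pos-1, pos-1+len(ref)).
    """
    v_start, v_end = pos - 1, pos - 1 + max(1, len(ref))
    return any(c == chrom and v_start < e and s < v_end for c, s, e in intervals)


def annotate_regions(
    variants: Iterable[SmallVariant],
    target_bed: Sequence[tuple[str, int, int]] | None = None,
    segdup_bed: Sequence[tuple[str, int, int]] | None = None,
) -> list[SmallVariant]:
    """Set on_target/in_segdup flags from BED interval overlap (in place)."""
    out = []
    for v in variants:
        if target_bed is not None:
            v.on_target = position_overlaps_bed(v.chrom, v.pos, v.ref, target_bed)
        if segdup_bed is not None:
            v.in_segdup = position_overlaps_bed(v.chrom, v.pos, v.ref, segdup_bed)
        out.append(v)
    return out


# -- CNV TSV ---------------------------------------------------------------------


def write_cnvs_tsv(segments: Iterable[CnvSegment], path: str | Path) -> None:
    rows = [
        dict(chrom=s.chrom, start=s.start, end=s.end, copy_number=s.copy_number,
             genes=",".join(s.genes), acmg_class=s.acmg_class or "",
             igv_flag=s.igv_flag, sample_id=s.sample_id)
        for s in segments
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "copy_number", "genes", "acmg_class",
                 "igv_flag", "sample_id"],
    ).to_csv(path, sep="\t", index=False)


def read_cnvs_tsv(path: str | Path) -> list[CnvSegment]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        out.append(
            CnvSegment(
                chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
                copy_number=float(row["copy_number"]),
                genes=tuple(g for g in row["genes"].split(",") if g),
                acmg_class=row["acmg_class"] or None,
                igv_flag=row.get("igv_flag", "not_reviewed") or "not_reviewed",
                sample_id=row.get("sample_id", ""),
            )
        )
    return out


# -- expression ------------------------------------------------------------------


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


# -- pipeline configuration --------------------------------------------------------


@dataclass
class PipelineConfig:
    """Thresholds of every analysis stage; defaults are the published rules."""

    seed: int = 1
    maf_cutoff: float = 0.01
    min_alt_reads: int = 8
    min_vaf: float = 0.05
    cadd_cutoff: float = 20.0
    cancervar_cutoff: float = 0.80
    tumor_only_popmax: float = 0.001
    amp_cutoff: float = 10.0
    tmb_cutoff: float = 5.0
    tmb_assay: str = "exome"  # panel | exome
    panel_length_bp: int = 3_040_053
    exome_length_bp: int = 38_289_292
    msi_cutoff: float = 10.0
    z_cutoff: float = 3.0
    min_reads: int = 20
    outlier_orientation: str = "per_gene"
    corr_method: str = "pearson"

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {f.name: getattr(self, f.name) for f in dc_fields(self)}, sort_keys=True
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)
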