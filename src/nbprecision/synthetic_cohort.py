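"""Synthetic tumor/normal/xenograft cohort generator.

Emulates the study design the downstream analysis assumes: relapsed tumors
(stage PZ) with matched normals, a subset of tumors engrafted in mice and
passaged to first (P1) and second (P2) generation, and 3D tumor-spheres grown
from P2 (P2_3D).  Every planted lesion (actionable SNV, CNV, over-expression
outlier, hypermutator, MSI-high, germline carrier) and every per-variant drift
event (retained/lost/gained, VAF rescaling) is recorded in a truth ledger so
parameter-recovery and lesion-recovery tests can replay the analysis against
known ground truth.

Drift model: crossing a generation, each variant is independently lost with a
stage-specific Bernoulli rate; retained variants have their VAF scaled
multiplicatively (inflation > 1 into mice, reflecting higher tumor purity;
deflation < 1 into 3D spheres) with small Gaussian jitter, clipped to [0, 1].
Planted actionable lesions are exempt from loss, mirroring the observed full
conservation of actionable alterations across generations.  Background VAFs
are Beta(a, b) draws truncated below at the clonal threshold, with a
configurable sub-threshold fraction to exercise the VAF filter.

Background variants are drawn so every filtration rule has both passing and
failing exemplars: caller-failed, segmental-duplication, common-polymorphism,
off-target, synonymous, low-read-support and sub-threshold-VAF records are
planted at fixed category rates alongside fully passing calls.
"""

from __future__ import annotations

import hashlib
import io as _io
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .actionability import AlterationCandidate, classify_events
from .cnv_selection import CnvSegment
from .knowledge import KnowledgeBase
from .model_fidelity import STAGES, LineageSet
from .variant_filters import SmallVariant, filter_somatic

__all__ = ["SimulationConfig", "Cohort", "simulate_cohort", "simulate_expression"]


class ConfigurationError(ValueError):
    """An invalid simulation or pipeline configuration value."""


# default genome model: 22 toy contigs with fixed target/segdup windows
_CONTIGS = tuple(f"chr{i}" for i in range(1, 23))
_TARGET = (1_000_000, 2_000_000)  # 0-based half-open, per contig
_SEGDUP = (1_500_000, 1_550_000)  # inside the target window
_OFFTARGET = (3_000_000, 4_000_000)
_BASES = ("A", "C", "G", "T")

# background category rates (fractions of n_background_variants_per_tumor)
_CATEGORY_RATES = {
    "caller_fail": 0.05,
    "segdup": 0.05,
    "common": 0.10,
    "off_target": 0.05,
    "synonymous": 0.15,
    "low_support": 0.05,
}

# oncogene targets for planted lesions (all present in the packaged kb)
_PLANT_SNV_GENES = ("ALK", "PIK3CA", "BRAF", "KRAS", "MET", "RET", "NTRK1")
_PLANT_AMP_GENES = ("MYCN", "MDM2", "CDK4", "CDK6", "CCND1", "AURKA")
_PLANT_DEL_GENES = ("CDKN2A", "CDKN2B", "ATRX", "TP53", "SMARCA4")
_PLANT_OUTLIER_GENES = (
    "CDK6", "CCND1", "HIF1A", "TOP2A", "AURKA", "TERT", "TNKS", "MYCN",
    "MDM2", "MDM4", "CDK4", "EGFR", "ERBB2", "FGFR1", "KIT", "CHEK1",
    "WEE1", "MTOR", "AKT1", "CUL4A", "PSMC2", "ALK",
)
_GERMLINE_GENES = ("MITF", "TSHR")


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; rates in [0,1], factors positive.

    The defaults are the study conditions: ~20% of origin variants lost at the
    first murine passage (>= 77-84% conservation), a 1.3x VAF inflation into
    mice (higher tumor purity), a milder P1->P2 shift, a VAF decrease and
    larger variant loss into 3D spheres, 16x planted expression outliers, and
    the panel/exome target lengths of the assays.
    """

    seed: int = 1
    n_patients: int = 19
    n_lineage_patients: int = 5
    n_3d_patients: int = 4
    n_background_variants_per_tumor: int = 200
    planted_actionable_snvs_per_tumor: int = 2
    planted_cnv_probability: float = 0.4
    planted_outlier_genes_per_sample: int = 1
    hypermutator_flag_probability: float = 0.05
    msi_high_probability: float = 0.0
    germline_carrier_probability: float = 0.12
    p1_variant_loss_rate: float = 0.20
    p2_additional_loss_rate: float = 0.05
    p3d_loss_rate: float = 0.30
    variant_gain_rate: float = 0.05
    vaf_inflation_p1: float = 1.3
    vaf_inflation_p2: float = 1.05
    vaf_deflation_3d: float = 0.7
    vaf_jitter_sd: float = 0.02
    vaf_beta_a: float = 2.0
    vaf_beta_b: float = 5.0
    min_clonal_vaf: float = 0.05
    subthreshold_fraction: float = 0.10
    n_genes_expression: int = 1000
    outlier_fold_change: float = 16.0
    panel_length_bp: int = 3_040_053
    exome_length_bp: int = 38_289_292

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rates = (
            "planted_cnv_probability",
            "hypermutator_flag_probability",
            "msi_high_probability",
            "germline_carrier_probability",
            "p1_variant_loss_rate",
            "p2_additional_loss_rate",
            "p3d_loss_rate",
            "variant_gain_rate",
            "subthreshold_fraction",
        )
        for name in rates:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        positives = (
            "vaf_inflation_p1",
            "vaf_inflation_p2",
            "vaf_deflation_3d",
            "vaf_beta_a",
            "vaf_beta_b",
            "outlier_fold_change",
            "panel_length_bp",
            "exome_length_bp",
        )
        for name in positives:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        counts = (
            "n_patients",
            "n_background_variants_per_tumor",
            "planted_actionable_snvs_per_tumor",
            "planted_outlier_genes_per_sample",
            "n_lineage_patients",
            "n_3d_patients",
            "n_genes_expression",
        )
        for name in counts:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.vaf_jitter_sd < 0:
            raise ConfigurationError(f"vaf_jitter_sd must be >= 0, got {self.vaf_jitter_sd}")
        if self.n_lineage_patients > self.n_patients:
            raise ConfigurationError("n_lineage_patients cannot exceed n_patients")
        if self.n_3d_patients > self.n_lineage_patients:
            raise ConfigurationError("n_3d_patients cannot exceed n_lineage_patients")
        if not 0.0 <= self.min_clonal_vaf <= 1.0:
            raise ConfigurationError(f"min_clonal_vaf must be in [0,1], got {self.min_clonal_vaf}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {f.name: getattr(self, f.name) for f in dc_fields(self)}, sort_keys=True
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class Cohort:
    """Everything one simulation run produced, plus the truth ledger."""

    config: SimulationConfig
    kb: KnowledgeBase
    patients: list[str]
    tumor_samples: list[str]  # PZ sample ids, one per tumor
    variants: dict[str, list[SmallVariant]]  # sample id (any stage) -> calls
    germline: dict[str, list[SmallVariant]]  # patient -> germline calls
    patients_without_normal: set[str]
    cnvs: dict[str, list[CnvSegment]]
    msi_scores: dict[str, float]
    expression: pd.DataFrame  # genes x samples (PZ + lineage stages)
    lineages: list[LineageSet]
    target_bed: list[tuple[str, int, int]]
    segdup_bed: list[tuple[str, int, int]]
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        """Write every generated table under ``outdir`` (TSV/BED/YAML)."""
        from pathlib import Path

        from .io import write_bed, write_cnvs_tsv, write_counts_tsv, write_variants_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(self.config.to_yaml())
        for sid in sorted(self.variants):
            write_variants_tsv(self.variants[sid], outdir / f"variants_{sid}.tsv")
        for pid in sorted(self.germline):
            if self.germline[pid]:
                write_variants_tsv(self.germline[pid], outdir / f"germline_{pid}.tsv")
        for sid in sorted(self.cnvs):
            write_cnvs_tsv(self.cnvs[sid], outdir / f"cnvs_{sid}.tsv")
        pd.DataFrame(
            sorted(self.msi_scores.items()), columns=["sample_id", "msi_score"]
        ).to_csv(outdir / "msi_scores.tsv", sep="\t", index=False)
        write_counts_tsv(self.expression, outdir / "expression_counts.tsv")
        write_bed(self.target_bed, outdir / "targets.bed")
        write_bed(self.segdup_bed, outdir / "segdups.bed")
        self.kb.write(outdir / "kb_genes.tsv", outdir / "kb_drugs.tsv")
        self.truth.to_csv(outdir / "truth_ledger.tsv", sep="\t", index=False)

    def checksum(self) -> str:
        """SHA-256 over a canonical serialization of all generated payloads."""
        h = hashlib.sha256()
        for sid in sorted(self.variants):
            for v in sorted(self.variants[sid], key=lambda v: v.key):
                h.update(
                    f"{sid}|{v.key}|{v.vaf:.6f}|{v.consequence}|{v.gene}|"
                    f"{v.alt_reads}|{v.depth}|{v.caller_pass}|{v.popmax_af}|"
                    f"{v.cadd_phred}|{v.cancervar_score}".encode()
                )
        for pid in sorted(self.germline):
            for v in sorted(self.germline[pid], key=lambda v: v.key):
                h.update(f"g|{pid}|{v.key}|{v.clinvar_class}|{v.intervar_class}".encode())
        for sid in sorted(self.cnvs):
            for s in sorted(self.cnvs[sid], key=lambda s: (s.chrom, s.start, s.end)):
                h.update(
                    f"{sid}|{s.chrom}:{s.start}-{s.end}|{s.copy_number}|{s.genes}|"
                    f"{s.acmg_class}|{s.igv_flag}".encode()
                )
        for sid in sorted(self.msi_scores):
            h.update(f"{sid}|{self.msi_scores[sid]:.6f}".encode())
        buf = _io.StringIO()
        self.expression.to_csv(buf, sep="\t")
        h.update(buf.getvalue().encode())
        buf = _io.StringIO()
        self.truth.sort_values(list(self.truth.columns)).to_csv(buf, sep="\t", index=False)
        h.update(buf.getvalue().encode())
        return h.hexdigest()


# -- internal helpers --------------------------------------------------------


def _draw_position(rng: np.random.Generator, region: tuple[int, int], used: set) -> tuple[str, int]:
    """A fresh (chrom, 1-based pos) inside the per-contig window ``region``."""
    while True:
        chrom = _CONTIGS[int(rng.integers(len(_CONTIGS)))]
        pos = int(rng.integers(region[0], region[1])) + 1  # 1-based
        if region == _TARGET and _SEGDUP[0] < pos <= _SEGDUP[1]:
            continue  # keep clean on-target draws out of the segdup window
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return _BASES[i], _BASES[j]


def _clonal_vaf(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    while True:
        v = float(rng.beta(cfg.vaf_beta_a, cfg.vaf_beta_b))
        if v >= cfg.min_clonal_vaf:
            return v


def _reads_for_vaf(rng: np.random.Generator, vaf: float, min_alt: int = 8) -> tuple[int, int, float]:
    """Depth/alt-read support consistent with a target VAF (alt/depth exact)."""
    depth = int(rng.integers(200, 401))
    alt = max(min_alt, min(depth, round(vaf * depth)))
    return alt, depth, alt / depth


def _expected_priority(gene: str, effect: str, event_class: str, kb: KnowledgeBase) -> str | None:
    """Replay the grading rules on a single candidate to get its priority."""
    cand = AlterationCandidate(
        patient_id="_", sample_id="_", event_class=event_class, gene=gene, effect=effect
    )
    events = classify_events([cand], kb)
    return events[0].priority if events else None


def _background_variant(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    kb_genes: Sequence[str],
    used: set,
    category: str,
    sample_id: str,
    gene_counter: list[int],
) -> SmallVariant:
    region = _TARGET
    caller_pass, in_segdup, on_target = True, False, True
    popmax: float | None = None
    consequence = "missense"
    if category == "caller_fail":
        caller_pass = False
    elif category == "segdup":
        in_segdup = True
        region = None  # position drawn inside the segdup window below
    elif category == "common":
        popmax = float(rng.uniform(0.011, 0.5))
    elif category == "off_target":
        on_target = False
        region = _OFFTARGET
    elif category == "synonymous":
        consequence = "synonymous"

    if region is None:
        while True:
            chrom = _CONTIGS[int(rng.integers(len(_CONTIGS)))]
            pos = int(rng.integers(_SEGDUP[0], _SEGDUP[1])) + 1
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
    else:
        chrom, pos = _draw_position(rng, region, used)
    ref, alt = _alleles(rng)

    if category == "subthreshold":
        vaf = float(rng.uniform(0.005, 0.045))
        depth = int(rng.integers(300, 501))
        alt_reads = max(8, round(vaf * depth))
        vaf = alt_reads / depth
    elif category == "low_support":
        depth = int(rng.integers(200, 401))
        alt_reads = int(rng.integers(1, 8))
        vaf = alt_reads / depth
    else:
        vaf = _clonal_vaf(rng, cfg)
        alt_reads, depth, vaf = _reads_for_vaf(rng, vaf)

    # a slice of passing background falls in knowledge-base genes (missense,
    # unknown effect) to exercise grading without planting anything actionable
    if category == "pass" and rng.random() < 0.10:
        gene = str(rng.choice(list(kb_genes)))
    else:
        gene_counter[0] += 1
        gene = f"BGD{gene_counter[0]:05d}"
        if category == "pass" and rng.random() < 0.25:  # never for "hyper"
            # consequence diversity, kept out of kb genes so no frameshift or
            # stopgain background can masquerade as an actionable LOF lesion
            consequence = str(
                rng.choice(["stopgain", "frameshift", "splice", "inframe_indel", "other_exonic"])
            )

    if rng.random() < 0.5:
        cadd = float(rng.uniform(0.0, 20.0))
    else:
        cadd = float(rng.uniform(20.5, 45.0))
    cancervar = None if rng.random() < 0.6 else float(rng.uniform(0.0, 1.0))
    if popmax is None and rng.random() < 0.3:
        popmax = float(rng.uniform(0.0, 0.009))

    return SmallVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vaf=vaf,
        sample_id=sample_id,
        gene=gene,
        consequence=consequence,
        caller_pass=caller_pass,
        popmax_af=popmax,
        cadd_phred=cadd,
        cancervar_score=cancervar,
        in_cosmic=bool(rng.random() < 0.1),
        alt_reads=alt_reads,
        depth=depth,
        in_segdup=in_segdup,
        on_target=on_target,
        effect="unknown",
    )


def _drift_variant(v: SmallVariant, new_vaf: float, sample_id: str) -> SmallVariant:
    alt = max(1, min(v.depth, round(new_vaf * v.depth)))
    return SmallVariant(
        chrom=v.chrom,
        pos=v.pos,
        ref=v.ref,
        alt=v.alt,
        vaf=alt / v.depth,
        sample_id=sample_id,
        gene=v.gene,
        consequence=v.consequence,
        caller_pass=True,
        popmax_af=v.popmax_af,
        cadd_phred=v.cadd_phred,
        cancervar_score=v.cancervar_score,
        in_cosmic=v.in_cosmic,
        alt_reads=alt,
        depth=v.depth,
        in_segdup=v.in_segdup,
        on_target=v.on_target,
        effect=v.effect,
    )


# -- main operations ---------------------------------------------------------


def simulate_cohort(config: SimulationConfig, kb: KnowledgeBase | None = None) -> Cohort:
    """Generate a full synthetic cohort; identical config gives identical output."""
    config.validate()
    cfg = config
    kb = kb or KnowledgeBase.load_default()
    rng = np.random.default_rng(cfg.seed)
    kb_genes = sorted(
        set(kb.genes["symbol"]) - {"IMMUNE_CHECKPOINT"} - set(_PLANT_SNV_GENES)
    )
    gene_counter = [0]

    patients = [f"Pz{i + 1:02d}" for i in range(cfg.n_patients)]
    truth_rows: list[dict] = []
    variants: dict[str, list[SmallVariant]] = {}
    germline: dict[str, list[SmallVariant]] = {}
    cnvs: dict[str, list[CnvSegment]] = {}
    msi_scores: dict[str, float] = {}
    patients_without_normal: set[str] = set(patients[:1]) if patients else set()

    target_bed = [(c, _TARGET[0], _TARGET[1]) for c in _CONTIGS]
    segdup_bed = [(c, _SEGDUP[0], _SEGDUP[1]) for c in _CONTIGS]

    cat_names = list(_CATEGORY_RATES)
    for pid in patients:
        sid = pid  # the PZ tumor sample carries the patient id
        used: set = set()
        calls: list[SmallVariant] = []

        # background: fixed category counts, remainder passing
        n_bg = cfg.n_background_variants_per_tumor
        counts = {c: int(round(r * n_bg)) for c, r in _CATEGORY_RATES.items()}
        counts["subthreshold"] = int(round(cfg.subthreshold_fraction * n_bg))
        counts["pass"] = max(0, n_bg - sum(counts.values()))
        for cat in cat_names + ["subthreshold", "pass"]:
            for _ in range(counts[cat]):
                calls.append(
                    _background_variant(rng, cfg, kb_genes, used, cat, sid, gene_counter)
                )

        # planted actionable SNVs: GOF hotspot missense in druggable oncogenes
        for _ in range(cfg.planted_actionable_snvs_per_tumor):
            gene = str(rng.choice(_PLANT_SNV_GENES))
            chrom, pos = _draw_position(rng, _TARGET, used)
            ref, alt = _alleles(rng)
            vaf = _clonal_vaf(rng, cfg)
            alt_reads, depth, vaf = _reads_for_vaf(rng, vaf)
            v = SmallVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, vaf=vaf, sample_id=sid,
                gene=gene, consequence="missense", caller_pass=True, popmax_af=None,
                cadd_phred=float(rng.uniform(25.0, 40.0)),
                cancervar_score=float(rng.uniform(0.85, 0.99)),
                in_cosmic=True, alt_reads=alt_reads, depth=depth, effect="GOF",
            )
            calls.append(v)
            truth_rows.append(
                dict(kind="planted_snv", patient_id=pid, sample_id=sid, gene=gene,
                     chrom=chrom, pos=pos, ref=ref, alt=alt, stage="PZ",
                     value=vaf,
                     expected_priority=_expected_priority(gene, "GOF", "SNV_INDEL", kb))
            )

        # hypermutator: enough extra passing missense to cross the TMB cutoff
        # on the exome assay the cohort is sequenced with
        if rng.random() < cfg.hypermutator_flag_probability:
            need = math.ceil(5.0 * cfg.exome_length_bp / 1e6) + 10
            kept_now, _ = filter_somatic(calls)
            have = sum(1 for v in kept_now if v.consequence == "missense" and v.vaf >= 0.05)
            for _ in range(max(0, need - have)):
                calls.append(
                    _background_variant(rng, cfg, kb_genes, used, "hyper", sid, gene_counter)
                )
            truth_rows.append(
                dict(kind="hypermutator", patient_id=pid, sample_id=sid, gene=None,
                     chrom=None, pos=None, ref=None, alt=None, stage="PZ",
                     value=None, expected_priority="VERY_HIGH")
            )

        variants[sid] = calls

        # CNV segments: planted actionable plus non-qualifying background
        segs: list[CnvSegment] = []
        chrom = _CONTIGS[int(rng.integers(len(_CONTIGS)))]
        start = int(rng.integers(_TARGET[0], _TARGET[1] - 100_000))
        segs.append(
            CnvSegment(chrom=chrom, start=start, end=start + 50_000,
                       copy_number=float(rng.integers(1, 7)),
                       genes=(f"BGD{gene_counter[0] + 1:05d}",),
                       acmg_class="VUS", igv_flag="passed", sample_id=sid)
        )
        gene_counter[0] += 1
        if rng.random() < cfg.planted_cnv_probability:
            if rng.random() < 0.5:
                gene = str(rng.choice(_PLANT_AMP_GENES))
                cn, kind, effect = float(rng.integers(10, 51)), "amplification", "GOF"
            else:
                gene = str(rng.choice(_PLANT_DEL_GENES))
                cn, kind, effect = 0.0, "deletion", "LOF"
            chrom = _CONTIGS[int(rng.integers(len(_CONTIGS)))]
            start = int(rng.integers(_TARGET[0], _TARGET[1] - 100_000))
            segs.append(
                CnvSegment(chrom=chrom, start=start, end=start + 80_000,
                           copy_number=cn, genes=(gene,), acmg_class="pathogenic",
                           igv_flag="passed", sample_id=sid)
            )
            truth_rows.append(
                dict(kind="planted_cnv", patient_id=pid, sample_id=sid, gene=gene,
                     chrom=chrom, pos=start, ref=None, alt=kind, stage="PZ",
                     value=cn,
                     expected_priority=_expected_priority(gene, effect, "CNV", kb))
            )
        cnvs[sid] = segs

        # MSI: low scores by default; optionally planted MSI-high
        if rng.random() < cfg.msi_high_probability:
            msi_scores[sid] = float(rng.uniform(10.0, 30.0))
            truth_rows.append(
                dict(kind="msi_high", patient_id=pid, sample_id=sid, gene=None,
                     chrom=None, pos=None, ref=None, alt=None, stage="PZ",
                     value=msi_scores[sid], expected_priority="VERY_HIGH")
            )
        else:
            msi_scores[sid] = float(rng.uniform(0.0, 5.0))

        # germline calls for patients with a matched normal
        if pid not in patients_without_normal:
            gcalls: list[SmallVariant] = []
            gused: set = set()
            for _ in range(20):  # benign/common germline background
                chrom, pos = _draw_position(rng, _TARGET, gused)
                ref, alt = _alleles(rng)
                vaf = float(rng.choice([0.5, 1.0]))
                depth = int(rng.integers(100, 200))
                gcalls.append(
                    SmallVariant(
                        chrom=chrom, pos=pos, ref=ref, alt=alt, vaf=vaf,
                        sample_id=f"{pid}-N", gene=f"BGD{gene_counter[0] + 1:05d}",
                        consequence="missense", caller_pass=True,
                        popmax_af=float(rng.uniform(0.02, 0.4)),
                        clinvar_class=str(rng.choice(["Benign", "Likely_benign", "VUS"])),
                        alt_reads=round(vaf * depth), depth=depth,
                    )
                )
                gene_counter[0] += 1
            if rng.random() < cfg.germline_carrier_probability:
                gene = str(rng.choice(_GERMLINE_GENES))
                chrom, pos = _draw_position(rng, _TARGET, gused)
                ref, alt = _alleles(rng)
                depth = int(rng.integers(100, 200))
                gcalls.append(
                    SmallVariant(
                        chrom=chrom, pos=pos, ref=ref, alt=alt, vaf=0.5,
                        sample_id=f"{pid}-N", gene=gene, consequence="missense",
                        caller_pass=True, popmax_af=float(rng.uniform(0.0, 0.0009)),
                        clinvar_class="Pathogenic", intervar_class="Pathogenic",
                        alt_reads=round(0.5 * depth), depth=depth,
                    )
                )
                truth_rows.append(
                    dict(kind="germline_carrier", patient_id=pid, sample_id=f"{pid}-N",
                         gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
                         stage="PZ", value=0.5, expected_priority=None)
                )
            germline[pid] = gcalls
        else:
            germline[pid] = []

    # lineages: serial passage with loss + VAF drift
    planted_keys: dict[str, set] = {
        pid: {
            (r["chrom"], r["pos"], r["ref"], r["alt"])
            for r in truth_rows
            if r["kind"] == "planted_snv" and r["patient_id"] == pid
        }
        for pid in patients
    }
    lineages: list[LineageSet] = []
    for pid in patients[: cfg.n_lineage_patients]:
        has_3d = patients.index(pid) < cfg.n_3d_patients
        stage_variants: dict[str, list[SmallVariant]] = {"PZ": variants[pid]}
        stage_cnvs: dict[str, list[CnvSegment]] = {"PZ": cnvs[pid]}
        transitions = [("PZ", "P1", cfg.p1_variant_loss_rate, cfg.vaf_inflation_p1),
                       ("P1", "P2", cfg.p2_additional_loss_rate, cfg.vaf_inflation_p2)]
        if has_3d:
            transitions.append(("P2", "P2_3D", cfg.p3d_loss_rate, cfg.vaf_deflation_3d))
        for origin, targ, loss_rate, scale in transitions:
            tsid = f"{pid}-{targ}"
            out: list[SmallVariant] = []
            used_t = {(v.chrom, v.pos) for v in stage_variants[origin]}
            for v in stage_variants[origin]:
                exempt = v.key in planted_keys[pid]
                if not exempt and rng.random() < loss_rate:
                    truth_rows.append(
                        dict(kind="variant_lost", patient_id=pid, sample_id=tsid,
                             gene=v.gene, chrom=v.chrom, pos=v.pos, ref=v.ref,
                             alt=v.alt, stage=targ, value=v.vaf,
                             expected_priority=None)
                    )
                    continue
                new_vaf = float(
                    np.clip(v.vaf * scale + rng.normal(0.0, cfg.vaf_jitter_sd), 0.0, 1.0)
                )
                nv = _drift_variant(v, new_vaf, tsid)
                out.append(nv)
                truth_rows.append(
                    dict(kind="variant_retained", patient_id=pid, sample_id=tsid,
                         gene=v.gene, chrom=v.chrom, pos=v.pos, ref=v.ref,
                         alt=v.alt, stage=targ, value=nv.vaf,
                         expected_priority=None)
                )
            n_gain = int(rng.binomial(len(stage_variants[origin]), cfg.variant_gain_rate))
            for _ in range(n_gain):
                nv = _background_variant(rng, cfg, kb_genes, used_t, "pass", tsid, gene_counter)
                out.append(nv)
                truth_rows.append(
                    dict(kind="variant_gained", patient_id=pid, sample_id=tsid,
                         gene=nv.gene, chrom=nv.chrom, pos=nv.pos, ref=nv.ref,
                         alt=nv.alt, stage=targ, value=nv.vaf,
                         expected_priority=None)
                )
            stage_variants[targ] = out
            variants[tsid] = out

            # CNVs conserved across passage; amplifications gain copies in mice
            seg_out: list[CnvSegment] = []
            for s in stage_cnvs[origin]:
                cn = s.copy_number
                if cn >= 10 and targ in {"P1", "P2"}:
                    cn = float(cn + rng.integers(0, 6))
                seg_out.append(
                    CnvSegment(chrom=s.chrom, start=s.start, end=s.end,
                               copy_number=cn, genes=s.genes, acmg_class=s.acmg_class,
                               igv_flag=s.igv_flag, sample_id=tsid)
                )
            stage_cnvs[targ] = seg_out
            cnvs[tsid] = seg_out

        sample_ids = {stage: (pid if stage == "PZ" else f"{pid}-{stage}")
                      for stage in stage_variants}
        lineages.append(
            LineageSet(patient_id=pid, variants=stage_variants, cnvs=stage_cnvs,
                       sample_ids=sample_ids)
        )

    # expression for all PZ tumors plus lineage stage samples
    expression, outlier_rows = simulate_expression(cfg, lineages, rng=rng,
                                                   extra_samples=patients, kb=kb)
    truth_rows.extend(outlier_rows)
    for lin in lineages:  # outlier calls are tracked per stage downstream
        for stage in lin.stages:
            lin.outlier_genes.setdefault(stage, set())
    for row in outlier_rows:
        for lin in lineages:
            for stage in lin.stages:
                if lin.sample_ids[stage] == row["sample_id"]:
                    lin.outlier_genes[stage].add(row["gene"])

    truth = pd.DataFrame.from_records(
        truth_rows,
        columns=["kind", "patient_id", "sample_id", "gene", "chrom", "pos",
                 "ref", "alt", "stage", "value", "expected_priority"],
    )
    return Cohort(
        config=cfg, kb=kb, patients=patients, tumor_samples=list(patients),
        variants=variants, germline=germline,
        patients_without_normal=patients_without_normal, cnvs=cnvs,
        msi_scores=msi_scores, expression=expression, lineages=lineages,
        target_bed=target_bed, segdup_bed=segdup_bed, truth=truth,
    )


def simulate_expression(
    config: SimulationConfig,
    lineages: Sequence[LineageSet],
    rng: np.random.Generator | None = None,
    extra_samples: Sequence[str] = (),
    kb: KnowledgeBase | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Count matrix (genes x samples) with planted per-sample over-expression.

    Samples of one lineage share a per-patient baseline shift, so
    within-lineage correlation exceeds between-lineage correlation in
    expectation.  Planted outlier genes have their expected counts multiplied
    by ``outlier_fold_change`` in exactly the designated sample.  Returns the
    matrix and the planted-outlier ledger rows (empty for fold change 1, where
    no planted gene is distinguishable from background).
    """
    cfg = config
    if cfg.n_genes_expression < 50:
        raise ConfigurationError(
            f"n_genes_expression must be >= 50, got {cfg.n_genes_expression}"
        )
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    kb = kb or KnowledgeBase.load_default()

    lineage_samples = [(lin.patient_id, lin.sample_ids[s]) for lin in lineages for s in lin.stages]
    lineage_sids = {sid for _, sid in lineage_samples}
    samples = [(pid, pid) for pid in extra_samples if pid not in lineage_sids]
    samples += lineage_samples

    outlier_pool = [g for g in _PLANT_OUTLIER_GENES if kb.has_gene(g)]
    gene_names = list(outlier_pool) + [
        f"GENE{i:05d}" for i in range(cfg.n_genes_expression - len(outlier_pool))
    ]
    n_genes = len(gene_names)

    base = rng.normal(5.0, 2.0, size=n_genes)  # log2 baseline per gene
    low = rng.random(n_genes) < 0.10  # low-count exemplars for the filter
    low[: len(outlier_pool)] = False  # druggable targets stay expressed
    base[low] = rng.normal(0.0, 1.0, size=int(low.sum()))
    # outlier targets are constitutively well-expressed oncogenes; a moderate
    # baseline keeps shot noise small relative to the planted fold change
    base[: len(outlier_pool)] = rng.normal(6.0, 1.0, size=len(outlier_pool))

    patient_ids = sorted({pid for pid, _ in samples})
    pat_effect = {
        pid: rng.normal(0.0, 0.4, size=n_genes) for pid in patient_ids
    }

    # assign planted genes per patient, without replacement across the cohort
    # while the pool lasts, so each gene is elevated in one patient's samples
    planted_per_patient: dict[str, list[str]] = {pid: [] for pid in patient_ids}
    plant = cfg.outlier_fold_change > 1.0 and cfg.planted_outlier_genes_per_sample > 0
    if plant:
        available = list(outlier_pool)
        for pid in patient_ids:
            for _ in range(cfg.planted_outlier_genes_per_sample):
                if not available:
                    available = [g for g in outlier_pool if g not in planted_per_patient[pid]]
                g = str(available.pop(int(rng.integers(len(available)))))
                planted_per_patient[pid].append(g)

    ledger: list[dict] = []
    cols = {}
    if not samples:  # empty cohort: an empty matrix, nothing planted
        return pd.DataFrame(index=gene_names), ledger
    for pid, sid in samples:
        log2_mu = base + pat_effect[pid] + rng.normal(0.0, 0.2, size=n_genes)
        lam = np.power(2.0, log2_mu) * float(rng.uniform(0.8, 1.2))
        # outlier lesions are conserved across a lineage's stages
        for g in planted_per_patient.get(pid, []):
            gi = gene_names.index(g)
            lam[gi] *= cfg.outlier_fold_change
            ledger.append(
                dict(kind="planted_outlier", patient_id=pid, sample_id=sid,
                     gene=g, chrom=None, pos=None, ref=None, alt=None,
                     stage="PZ" if sid == pid else sid.rsplit("-", 1)[-1],
                     value=cfg.outlier_fold_change,
                     expected_priority=_expected_priority(g, "GOF", "OVEREXPRESSION", kb))
            )
        cols[sid] = rng.poisson(lam)

    matrix = pd.DataFrame(cols, index=gene_names)
    return matrix, ledger
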