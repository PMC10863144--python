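"""End-to-end orchestration: filtration -> CNV selection -> burden ->
expression outliers -> actionability -> model fidelity.

Stage order is fixed and every stage logs its audit.  Outputs are
deterministic given the cohort and configuration; all iteration is over sorted
sample identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import expression_analysis as expr
from .actionability import (
    ActionableEvent,
    AlterationCandidate,
    CohortSummary,
    classify_events,
    summarize_cohort,
)
from .burden_metrics import TmbResult, call_msi_high, compute_tmb
from .cnv_selection import SelectedCnv, select_actionable_cnvs
from .io import PipelineConfig, write_variants_tsv
from .model_fidelity import (
    MannWhitneyResult,
    SimilarityResult,
    build_vaf_matrix,
    conserved_fraction,
    similarity_suite,
    track_actionable,
    vaf_shift_test,
)
from .synthetic_cohort import Cohort
from .variant_filters import (
    FilterAudit,
    SmallVariant,
    filter_germline,
    filter_somatic,
    filter_tumor_only,
    prioritize_pathogenic,
)

__all__ = ["PipelineError", "PipelineResult", "FidelityReport", "run_pipeline", "derive_effect"]

logger = logging.getLogger(__name__)


class _SkipStage(Exception):
    """Internal: a stage has no applicable input (e.g. no expression samples)."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending sample if known."""

    def __init__(self, stage: str, message: str, sample: str | None = None):
        self.stage = stage
        self.sample = sample
        where = f"stage {stage}" + (f", sample {sample}" if sample else "")
        super().__init__(f"{where}: {message}")


def derive_effect(v: SmallVariant) -> str:
    """Functional direction of a variant for mechanism-concordance checks.

    The annotated ``effect`` wins when present; otherwise truncating
    consequences (frameshift, stopgain) default to loss-of-function and
    everything else stays unknown (a missense is only GOF when hotspot-flagged
    upstream, which arrives via the ``effect`` field).
    """
    if v.effect in {"LOF", "GOF"}:
        return v.effect
    if v.consequence in {"frameshift", "stopgain"}:
        return "LOF"
    return "unknown"


@dataclass
class FidelityReport:
    vaf_matrix: pd.DataFrame | None = None
    similarity: SimilarityResult | None = None
    conserved: pd.DataFrame = field(default_factory=pd.DataFrame)
    vaf_shifts: dict[str, MannWhitneyResult] = field(default_factory=dict)
    trajectories: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class PipelineResult:
    cohort: Cohort
    config: PipelineConfig
    kept: dict[str, list[SmallVariant]]
    audits: dict[str, FilterAudit]
    pathogenic: dict[str, list[SmallVariant]]
    germline_hits: dict[str, list[SmallVariant]]
    selected_cnvs: dict[str, list[SelectedCnv]]
    tmb: dict[str, TmbResult]
    msi_high: dict[str, bool]
    outlier_calls: set[tuple[str, str]]
    events: list[ActionableEvent]
    summary: CohortSummary
    fidelity: FidelityReport


def run_pipeline(
    cohort: Cohort, config: PipelineConfig | None = None, outdir: str | Path | None = None
) -> PipelineResult:
    """Run every analysis stage on a cohort and optionally write result tables."""
    cfg = config or PipelineConfig()

    # 1. small-variant filtration + pathogenicity prioritization
    kept: dict[str, list[SmallVariant]] = {}
    audits: dict[str, FilterAudit] = {}
    pathogenic: dict[str, list[SmallVariant]] = {}
    try:
        for sid in sorted(cohort.variants):
            patient = sid.split("-")[0]
            if patient in cohort.patients_without_normal:
                k, audit = filter_tumor_only(
                    cohort.variants[sid], popmax_cutoff=cfg.tumor_only_popmax,
                    maf_cutoff=cfg.maf_cutoff, min_alt_reads=cfg.min_alt_reads,
                    min_vaf=cfg.min_vaf,
                )
            else:
                k, audit = filter_somatic(
                    cohort.variants[sid], maf_cutoff=cfg.maf_cutoff,
                    min_alt_reads=cfg.min_alt_reads, min_vaf=cfg.min_vaf,
                )
            kept[sid], audits[sid] = k, audit
            pathogenic[sid] = prioritize_pathogenic(
                k, cadd_cutoff=cfg.cadd_cutoff, cancervar_cutoff=cfg.cancervar_cutoff
            )
            logger.info("filtration %s: %d -> %d kept, %d pathogenic",
                        sid, audit.input_count, audit.kept_count, len(pathogenic[sid]))
    except Exception as exc:  # pragma: no cover - defensive wrapping
        raise PipelineError("filtration", str(exc)) from exc

    # 2. germline screening on matched normals
    germline_hits: dict[str, list[SmallVariant]] = {}
    try:
        predisposition = cohort.kb.predisposition_genes()
        for pid in sorted(cohort.germline):
            if pid in cohort.patients_without_normal or not cohort.germline[pid]:
                continue
            hits, _ = filter_germline(cohort.germline[pid], predisposition,
                                      maf_cutoff=cfg.maf_cutoff)
            if hits:
                germline_hits[pid] = hits
    except Exception as exc:
        raise PipelineError("germline", str(exc)) from exc

    # 3. CNV selection (origin tumors)
    selected_cnvs: dict[str, list[SelectedCnv]] = {}
    try:
        for sid in sorted(cohort.cnvs):
            selected_cnvs[sid] = select_actionable_cnvs(
                cohort.cnvs[sid], cohort.kb, amp_cutoff=cfg.amp_cutoff
            )
    except Exception as exc:
        raise PipelineError("cnv_selection", str(exc)) from exc

    # 4. burden metrics on origin tumors
    tmb: dict[str, TmbResult] = {}
    msi_high: dict[str, bool] = {}
    try:
        tmb_length = cfg.panel_length_bp if cfg.tmb_assay == "panel" else cfg.exome_length_bp
        for sid in cohort.tumor_samples:
            tmb[sid] = compute_tmb(
                kept[sid], target_length_bp=tmb_length,
                min_vaf=cfg.min_vaf, actionable_cutoff=cfg.tmb_cutoff, sample_id=sid,
            )
            msi_high[sid] = call_msi_high(cohort.msi_scores[sid], cutoff=cfg.msi_cutoff)
    except Exception as exc:
        raise PipelineError("burden", str(exc)) from exc

    # 5. expression outliers: per-gene z over the origin-tumor cohort; model
    # stages are scored against the origin cohort's per-gene location/scale
    outlier_calls: set[tuple[str, str]] = set()
    try:
        if cohort.expression.shape[1] == 0:
            raise _SkipStage
        counts = expr.filter_low_counts(cohort.expression, min_reads=cfg.min_reads)
        _, log2cpm = expr.cpm_log2(counts)
        pz_cols = [s for s in cohort.tumor_samples if s in log2cpm.columns]
        if len(pz_cols) >= 2:
            outlier_calls = expr.detect_outliers(
                log2cpm[pz_cols], z_cutoff=cfg.z_cutoff,
                orientation=cfg.outlier_orientation,
            )
            z_ref = expr.zscore_against_reference(log2cpm, pz_cols)
            for lin in cohort.lineages:
                for stage in lin.stages:
                    sid = lin.sample_ids[stage]
                    if sid in z_ref.columns:
                        lin.outlier_genes[stage] = set(
                            z_ref.index[z_ref[sid] >= cfg.z_cutoff]
                        )
    except _SkipStage:
        pass
    except Exception as exc:
        raise PipelineError("expression", str(exc)) from exc

    # 6. actionability
    try:
        cohort.kb.validate()
        candidates: list[AlterationCandidate] = []
        for sid in cohort.tumor_samples:
            pid = sid.split("-")[0]
            for v in pathogenic[sid]:
                if not cohort.kb.has_gene(v.gene):
                    continue
                candidates.append(
                    AlterationCandidate(
                        patient_id=pid, sample_id=sid, event_class="SNV_INDEL",
                        gene=v.gene, effect=derive_effect(v),
                        provenance="filter_somatic+prioritize_pathogenic",
                        detail={"key": v.key, "vaf": v.vaf},
                    )
                )
            for sel in selected_cnvs.get(sid, []):
                candidates.append(
                    AlterationCandidate(
                        patient_id=pid, sample_id=sid, event_class="CNV",
                        gene=sel.gene,
                        effect="LOF" if sel.kind == "deletion" else "GOF",
                        provenance="select_actionable_cnvs",
                        detail={"kind": sel.kind, "copy_number": sel.segment.copy_number},
                    )
                )
            for gene, sample in sorted(outlier_calls):
                if sample == sid and cohort.kb.has_gene(gene):
                    candidates.append(
                        AlterationCandidate(
                            patient_id=pid, sample_id=sid, event_class="OVEREXPRESSION",
                            gene=gene, effect="GOF", provenance="detect_outliers",
                        )
                    )
            if tmb[sid].actionable:
                candidates.append(
                    AlterationCandidate(
                        patient_id=pid, sample_id=sid, event_class="HYPERMUTATION",
                        provenance="compute_tmb", detail={"tmb": tmb[sid].tmb},
                    )
                )
            if msi_high[sid]:
                candidates.append(
                    AlterationCandidate(
                        patient_id=pid, sample_id=sid, event_class="MSI_HIGH",
                        provenance="call_msi_high",
                        detail={"score": cohort.msi_scores[sid]},
                    )
                )
        events = classify_events(candidates, cohort.kb)
        summary = summarize_cohort(events, cohort.tumor_samples)
    except Exception as exc:
        raise PipelineError("actionability", str(exc)) from exc

    # 7. model fidelity
    fidelity = FidelityReport()
    try:
        if cohort.lineages:
            fidelity.vaf_matrix = build_vaf_matrix(cohort.lineages)
            fidelity.similarity = similarity_suite(
                fidelity.vaf_matrix, corr_method=cfg.corr_method
            )
            pairs = [("PZ", "P1"), ("PZ", "P2"), ("P1", "P2"),
                     ("P2", "P2_3D"), ("P1", "P2_3D")]
            rows = []
            for lin in cohort.lineages:
                rare_missense = {
                    stage: [
                        v for v in lin.variants[stage]
                        if v.consequence == "missense"
                        and (v.popmax_af is None or v.popmax_af <= cfg.maf_cutoff)
                    ]
                    for stage in lin.stages
                }
                for origin, target in pairs:
                    if origin in lin.stages and target in lin.stages:
                        shared, frac = conserved_fraction(
                            rare_missense[origin], rare_missense[target]
                        )
                        rows.append(
                            dict(patient_id=lin.patient_id, origin=origin,
                                 target=target, shared=shared, fraction=frac)
                        )
            fidelity.conserved = pd.DataFrame(rows)
            stage_vafs: dict[str, list[float]] = {}
            for lin in cohort.lineages:
                for stage in lin.stages:
                    stage_vafs.setdefault(stage, []).extend(
                        v.vaf for v in lin.variants[stage]
                    )
            for a, b in [("PZ", "P1"), ("P1", "P2"), ("P2", "P2_3D")]:
                if stage_vafs.get(a) and stage_vafs.get(b):
                    fidelity.vaf_shifts[f"{a}_vs_{b}"] = vaf_shift_test(
                        stage_vafs[a], stage_vafs[b]
                    )
            trajs = [track_actionable(events, lin) for lin in cohort.lineages]
            trajs = [t for t in trajs if not t.empty]
            if trajs:
                fidelity.trajectories = pd.concat(trajs, ignore_index=True)
    except Exception as exc:
        raise PipelineError("fidelity", str(exc)) from exc

    result = PipelineResult(
        cohort=cohort, config=cfg, kept=kept, audits=audits, pathogenic=pathogenic,
        germline_hits=germline_hits, selected_cnvs=selected_cnvs, tmb=tmb,
        msi_high=msi_high, outlier_calls=outlier_calls, events=events,
        summary=summary, fidelity=fidelity,
    )
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    """Write the pipeline's tables as TSV under ``outdir`` (deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for sid in sorted(result.kept):
        write_variants_tsv(result.kept[sid], outdir / f"kept_{sid}.tsv")
    pd.DataFrame(
        [
            dict(sample_id=sid, input=a.input_count, kept=a.kept_count,
                 **{f"removed_{r}": n for r, n in a.removed_by_rule.items()})
            for sid, a in sorted(result.audits.items())
        ]
    ).to_csv(outdir / "filter_audit.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            dict(patient_id=e.patient_id, sample_id=e.sample_id,
                 event_class=e.event_class, gene=e.gene or "", pathway=e.pathway,
                 priority=e.priority,
                 drugs=";".join(e.drugs["drug"]), provenance=e.provenance)
            for e in result.events
        ]
    ).to_csv(outdir / "actionable_events.tsv", sep="\t", index=False)
    result.summary.matrix.to_csv(outdir / "summary_matrix.tsv", sep="\t")

    pd.DataFrame(
        [dict(sample_id=sid, missense=t.missense_count, tmb=t.tmb,
              actionable=t.actionable) for sid, t in sorted(result.tmb.items())]
    ).to_csv(outdir / "tmb.tsv", sep="\t", index=False)

    if not result.fidelity.conserved.empty:
        result.fidelity.conserved.to_csv(outdir / "conserved_fractions.tsv",
                                         sep="\t", index=False)
    if result.fidelity.vaf_shifts:
        pd.DataFrame(
            [dict(comparison=k, u=r.u_statistic, p_value=r.p_value,
                  median_a=r.median_a, median_b=r.median_b, method=r.method)
             for k, r in sorted(result.fidelity.vaf_shifts.items())]
        ).to_csv(outdir / "vaf_shift_tests.tsv", sep="\t", index=False)
    if not result.fidelity.trajectories.empty:
        result.fidelity.trajectories.to_csv(outdir / "actionable_trajectories.tsv",
                                            sep="\t", index=False)
    if result.fidelity.similarity is not None:
        result.fidelity.similarity.correlation.to_csv(
            outdir / "vaf_correlation.tsv", sep="\t"
        )
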