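"""Genomic fidelity of xenograft generations and 3D tumor-sphere models.

Patient tumors (PZ) serially passaged in mice (P1, P2) and 3D spheres grown
from P2 (P2_3D) are compared to their originating tumors through a
samples-by-variants VAF matrix: pairwise correlation, Ward-linkage hierarchical
clustering on Euclidean distances, PCA, conserved-variant fractions, and
Mann-Whitney tests on pooled per-stage VAF distributions.

A variant is identified by (chrom, 1-based position, ref, alt) everywhere; a
variant not called in a sample contributes 0 to that sample's row of the VAF
matrix (a missing-aware mode is available for sensitivity checks).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .actionability import ActionableEvent
from .cnv_selection import CnvSegment
from .variant_filters import SmallVariant

__all__ = [
    "STAGES",
    "LineageSet",
    "SimilarityResult",
    "MannWhitneyResult",
    "build_vaf_matrix",
    "similarity_suite",
    "conserved_fraction",
    "vaf_shift_test",
    "track_actionable",
]

logger = logging.getLogger(__name__)

STAGES = ("PZ", "P1", "P2", "P2_3D")

VariantKey = tuple[str, int, str, str]


@dataclass
class LineageSet:
    """One patient's samples across the available model stages."""

    patient_id: str
    variants: dict[str, list[SmallVariant]]  # stage -> calls
    cnvs: dict[str, list[CnvSegment]] = field(default_factory=dict)
    outlier_genes: dict[str, set[str]] = field(default_factory=dict)
    sample_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.variants) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels {sorted(bad)}; expected {STAGES}")
        for stage in self.variants:
            self.sample_ids.setdefault(stage, f"{self.patient_id}-{stage}")

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(s for s in STAGES if s in self.variants)

    def variant_keys(self, stage: str) -> set[VariantKey]:
        return {v.key for v in self.variants[stage]}


def build_vaf_matrix(
    lineages: Iterable[LineageSet] | Mapping[str, Sequence[SmallVariant]],
    zero_fill: bool = True,
) -> pd.DataFrame:
    """Samples-by-variant-keys VAF matrix over the union of called variants.

    Entries are the called VAF, 0 where the variant is absent from a sample
    (NaN with ``zero_fill=False``).  Duplicate keys within one sample are an
    input error.
    """
    if isinstance(lineages, Mapping):
        per_sample = {sid: list(vs) for sid, vs in lineages.items()}
    else:
        per_sample = {}
        for lin in lineages:
            for stage in lin.stages:
                per_sample[lin.sample_ids[stage]] = lin.variants[stage]
    if len(per_sample) < 2:
        raise ValueError("VAF matrix needs >= 2 samples")
    rows: dict[str, dict[VariantKey, float]] = {}
    for sid, variants in per_sample.items():
        row: dict[VariantKey, float] = {}
        for v in variants:
            if v.key in row:
                raise ValueError(f"duplicate variant key {v.key} in sample {sid}")
            row[v.key] = v.vaf
        rows[sid] = row
    all_keys = sorted({k for row in rows.values() for k in row})
    fill = 0.0 if zero_fill else np.nan
    mat = pd.DataFrame(
        [[rows[sid].get(k, fill) for k in all_keys] for sid in rows],
        index=list(rows),
        columns=[f"{c}:{p}:{r}>{a}" for c, p, r, a in all_keys],
    )
    return mat


@dataclass
class SimilarityResult:
    correlation: pd.DataFrame  # samples x samples
    corr_method: str
    linkage: np.ndarray  # scipy condensed linkage (Ward on Euclidean)
    pca_coords: pd.DataFrame  # samples x components
    explained_variance: np.ndarray  # fractions
    dropped_features: list[str]


def similarity_suite(
    matrix: pd.DataFrame, corr_method: str = "pearson"
) -> SimilarityResult:
    """Pairwise correlation, Ward clustering and PCA on a samples-by-features matrix.

    Constant features carry no signal for correlation distance and are dropped
    with a notice; an all-constant matrix is a degenerate input.  PCA centers
    features but does not rescale them (VAFs share a scale).
    """
    if corr_method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {corr_method!r}")
    if matrix.shape[0] < 2:
        raise ValueError("similarity suite needs >= 2 samples")
    variances = matrix.var(axis=0, ddof=0)
    dropped = list(matrix.columns[variances == 0])
    kept = matrix.loc[:, variances > 0]
    if kept.shape[1] == 0:
        raise ValueError("degenerate input: all features are constant")
    if dropped:
        logger.info("dropped %d constant feature(s)", len(dropped))
    corr = kept.T.corr(method=corr_method)
    linkage = hierarchy.linkage(kept.to_numpy(), method="ward", metric="euclidean")
    n_comp = min(kept.shape[0], kept.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(kept.to_numpy())
    pca_coords = pd.DataFrame(
        coords, index=kept.index, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    return SimilarityResult(
        correlation=corr,
        corr_method=corr_method,
        linkage=linkage,
        pca_coords=pca_coords,
        explained_variance=pca.explained_variance_ratio_,
        dropped_features=dropped,
    )


def conserved_fraction(
    origin: Iterable[VariantKey] | Iterable[SmallVariant],
    target: Iterable[VariantKey] | Iterable[SmallVariant],
) -> tuple[int, float | None]:
    """Shared-variant count and the fraction of origin variants conserved.

    Sets are keyed by (chrom, pos, ref, alt).  With an empty origin the
    fraction is undefined and reported as None.
    """

    def keys(xs: Iterable) -> set[VariantKey]:
        return {x.key if isinstance(x, SmallVariant) else tuple(x) for x in xs}

    o, t = keys(origin), keys(target)
    shared = len(o & t)
    return shared, (shared / len(o) if o else None)


@dataclass
class MannWhitneyResult:
    u_statistic: float  # U of group a
    p_value: float  # two-sided
    median_a: float
    median_b: float
    method: str  # exact | asymptotic


_EXACT_MAX_N = 20


def vaf_shift_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U comparing two pooled VAF distributions.

    Small pooled samples (n_a + n_b <= 20) use exact enumeration over all
    rank assignments (midranks for ties); larger samples use the normal
    approximation with tie and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    if n_a + n_b <= _EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        obs_u = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
        mu = n_a * n_b / 2.0
        obs_dev = abs(obs_u - mu)
        total = math.comb(n_a + n_b, n_a)
        count = 0
        for idx in itertools.combinations(range(n_a + n_b), n_a):
            u = sum(ranks[i] for i in idx) - n_a * (n_a + 1) / 2
            if abs(u - mu) >= obs_dev - 1e-12:
                count += 1
        return MannWhitneyResult(
            u_statistic=obs_u,
            p_value=count / total,
            median_a=float(np.median(a)),
            median_b=float(np.median(b)),
            method="exact",
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        method="asymptotic",
    )


def track_actionable(
    events: Sequence[ActionableEvent], lineage: LineageSet
) -> pd.DataFrame:
    """Trajectories of origin-tumor actionable events across model stages.

    For SNV/INDEL events: VAF per stage (None where the variant is not called,
    never 0).  For CNV events: copy number of a segment overlapping the gene.
    For over-expression events: presence of the outlier call.  One row per
    event, one ``value_<stage>`` column per stage present in the lineage.
    """
    records = []
    for e in events:
        if e.patient_id != lineage.patient_id:
            continue
        row: dict = {
            "patient_id": e.patient_id,
            "event_class": e.event_class,
            "gene": e.gene,
        }
        for stage in lineage.stages:
            value = None
            if e.event_class == "SNV_INDEL":
                key = tuple(e.detail["key"])
                hit = [v for v in lineage.variants[stage] if v.key == key]
                value = hit[0].vaf if hit else None
            elif e.event_class == "CNV":
                segs = [
                    s for s in lineage.cnvs.get(stage, []) if e.gene in s.genes
                ]
                value = max((s.copy_number for s in segs), default=None)
            elif e.event_class == "OVEREXPRESSION":
                stage_outliers = lineage.outlier_genes.get(stage)
                value = (e.gene in stage_outliers) if stage_outliers is not None else None
            row[f"value_{stage}"] = value
        records.append(row)
    return pd.DataFrame.from_records(records)
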