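"""Expression normalization and over-expression outlier detection.

Raw gene-level counts are filtered for low expression (a gene is dropped iff
it fails to reach ``min_reads`` in every sample), normalized to counts per
million on the retained gene set, log2-transformed with a pseudocount, and
standardized to Z-scores.  Genes with Z >= 3 (inclusive) are called as
over-expression outliers.  Preservation of outlier sets across tumor
generations is tested with a hypergeometric upper-tail overlap test.

Two Z-score orientations are supported.  ``per_sample`` standardizes each
sample over its genes (a gene is extreme relative to that sample's expression
distribution); ``per_gene`` standardizes each gene over the cohort (a sample
is extreme for that gene).  ``per_sample`` is the default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_low_counts",
    "cpm_log2",
    "zscore",
    "detect_outliers",
    "outlier_overlap_test",
]


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.empty:
        raise ValueError("empty count matrix")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")


def filter_low_counts(
    counts: pd.DataFrame, min_reads: int = 20, mode: str = "max"
) -> pd.DataFrame:
    """Drop genes (rows) with fewer than ``min_reads`` reads in all samples.

    ``mode='max'`` (default) removes a gene iff its maximum count across
    samples is below ``min_reads``; ``mode='sum'`` applies the threshold to the
    gene's total count instead.
    """
    _check_counts(counts)
    if mode == "max":
        keep = counts.max(axis=1) >= min_reads
    elif mode == "sum":
        keep = counts.sum(axis=1) >= min_reads
    else:
        raise ValueError(f"unknown low-count mode {mode!r}")
    return counts.loc[keep]


def cpm_log2(
    counts: pd.DataFrame, pseudocount: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts-per-million and log2(CPM + pseudocount) layers.

    Library sizes are the per-sample column sums of the matrix as given, i.e.
    computed after any gene filtering, matching the fixed pipeline order
    (filter, then normalize).
    """
    _check_counts(counts)
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = counts / lib * 1e6
    log2cpm = np.log2(cpm + pseudocount)
    return cpm, log2cpm


def zscore(log2cpm: pd.DataFrame, orientation: str = "per_sample") -> pd.DataFrame:
    """Z-scores of log2 CPM; columns (per_sample) or rows (per_gene) standardized.

    A zero-variance axis yields all-NaN scores there (degenerate; no calls).
    """
    if orientation == "per_sample":
        if log2cpm.shape[0] < 2:
            raise ValueError("per_sample standardization needs >= 2 genes")
        mean, sd = log2cpm.mean(axis=0), log2cpm.std(axis=0, ddof=0)
        z = (log2cpm - mean) / sd.replace(0.0, np.nan)
    elif orientation == "per_gene":
        if log2cpm.shape[1] < 2:
            raise ValueError("per_gene standardization needs >= 2 samples")
        mean, sd = log2cpm.mean(axis=1), log2cpm.std(axis=1, ddof=0)
        z = log2cpm.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return z


def zscore_against_reference(
    log2cpm: pd.DataFrame, reference_samples: list[str]
) -> pd.DataFrame:
    """Per-gene Z-scores of every sample against a reference cohort's mean/SD.

    Used to ask whether a xenograft or 3D-sphere sample preserves an
    over-expression call made in the tumor cohort: the gene's location and
    scale come from the reference (e.g. all origin tumors), so model samples
    neither dilute nor inflate the standardization.
    """
    missing = set(reference_samples) - set(log2cpm.columns)
    if missing:
        raise ValueError(f"reference samples absent from matrix: {sorted(missing)}")
    if len(reference_samples) < 2:
        raise ValueError("reference standardization needs >= 2 reference samples")
    ref = log2cpm[list(reference_samples)]
    mean, sd = ref.mean(axis=1), ref.std(axis=1, ddof=0)
    return log2cpm.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)


def detect_outliers(
    log2cpm: pd.DataFrame, z_cutoff: float = 3.0, orientation: str = "per_sample"
) -> set[tuple[str, str]]:
    """Over-expression calls: (gene, sample) pairs with Z >= ``z_cutoff`` (inclusive)."""
    z = zscore(log2cpm, orientation=orientation)
    genes, samples = np.nonzero((z >= z_cutoff).to_numpy())
    return {(z.index[g], z.columns[s]) for g, s in zip(genes, samples)}


def outlier_overlap_test(
    set_a: set, set_b: set, universe_size: int
) -> tuple[int, float]:
    """Overlap count and hypergeometric upper-tail p-value.

    p = P[X >= |A & B|] with X ~ Hypergeometric(universe_size, |A|, |B|): the
    chance of at least the observed overlap when B is drawn uniformly from a
    universe containing A.
    """
    set_a, set_b = set(set_a), set(set_b)
    if universe_size < len(set_a | set_b):
        raise ValueError(
            f"universe_size {universe_size} smaller than |A union B| = {len(set_a | set_b)}"
        )
    overlap = len(set_a & set_b)
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(set_a), len(set_b)))
    return overlap, min(p, 1.0)
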