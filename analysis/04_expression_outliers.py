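#!/usr/bin/env python
"""Expression normalization, over-expression outliers, and outlier-set overlap.

Counts are filtered (genes below 20 reads in every sample dropped), CPM
normalized and log2 transformed; genes with Z >= 3 are over-expression calls.
A hypergeometric overlap test asks whether the outlier gene sets of origin
tumors are preserved in first-generation xenografts.
"""

import argparse
from pathlib import Path

import pandas as pd

from nbprecision import SimulationConfig, simulate_cohort
from nbprecision.expression_analysis import (
    cpm_log2,
    detect_outliers,
    filter_low_counts,
    outlier_overlap_test,
    zscore_against_reference,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/expression"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(SimulationConfig(seed=args.seed))
    counts = filter_low_counts(cohort.expression)
    print(f"genes: {cohort.expression.shape[0]} -> {counts.shape[0]} after "
          f"low-count filtering; samples: {counts.shape[1]}")
    _, log2cpm = cpm_log2(counts)

    pz = [s for s in cohort.tumor_samples if s in log2cpm.columns]
    calls = detect_outliers(log2cpm[pz], z_cutoff=3.0, orientation="per_gene")
    pd.DataFrame(sorted(calls), columns=["gene", "sample_id"]).to_csv(
        args.outdir / "overexpression_calls.tsv", sep="\t", index=False)
    print(f"over-expression calls in origin tumors: {len(calls)}")

    # preservation in first-generation xenografts, scored on the tumor cohort's
    # per-gene location/scale
    z_ref = zscore_against_reference(log2cpm, pz)
    rows = []
    for lin in cohort.lineages:
        if "P1" not in lin.stages:
            continue
        pz_genes = {g for g, s in calls if s == lin.sample_ids["PZ"]}
        p1_sid = lin.sample_ids["P1"]
        p1_genes = set(z_ref.index[z_ref[p1_sid] >= 3.0]) if p1_sid in z_ref else set()
        overlap, p = outlier_overlap_test(pz_genes, p1_genes, counts.shape[0])
        rows.append(dict(patient_id=lin.patient_id, pz_outliers=len(pz_genes),
                         p1_outliers=len(p1_genes), overlap=overlap,
                         hypergeom_p=p))
    df = pd.DataFrame(rows)
    df.to_csv(args.outdir / "outlier_overlap.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
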