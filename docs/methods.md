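# Methods

## What the pipeline models

The package implements the downstream analysis of a precision-medicine
workflow for relapsed neuroblastoma: annotated somatic and germline calls,
copy-number segments, and raw expression counts come in; filtered and
prioritized variants, actionability-graded events, burden metrics, and a
genomic-fidelity report on xenograft/3D models come out. Upstream engines
(aligners, MuTect2/HaplotypeCaller, FREEC, ANNOVAR/AnnotSV-style annotation,
RNA quantification, the MSI scorer) are consumed, never re-implemented: their
outputs are the pipeline's inputs.

## Filtration cascades

Filters are ordered predicates over one record at a time; the kept set is the
intersection of the single-rule kept sets, so rule order affects only the
audit (first-failing-rule attribution), never membership. The audit conserves
records (`kept + Σ removed = input`) by construction and is asserted on every
run.

Choices where the written rules were ambiguous:

* **Read support.** "Fewer than 8 reads and VAF below 5%" is implemented as
  two independent requirements (alt reads ≥ 8 AND VAF ≥ 5%): the permissive
  reading would keep 7-read/60%-VAF artifacts, contradicting the rule's
  false-positive-removal purpose. Both thresholds are configurable, and the
  count is of alternate-supporting reads, not total depth.
* **Rarity.** `popmax_af` is the maximum over whatever population panels the
  annotation provides; an absent value means "never observed" and passes. The
  1% cutoff is strict: exactly 1% is kept.
* **Tumor-only rule.** Read as COSMIC-rescue: a call is removed iff
  popmax > 0.001 AND it is not in COSMIC (membership rescues). A strict mode
  (`cosmic_rescue=False`) removes on popmax alone.
* **Coordinates.** Variants are 1-based (VCF convention); BED intervals are
  0-based half-open; the conversion lives in one routine
  (`position_overlaps_bed`), and an INDEL overlaps a region if any affected
  reference base does.

## Burden metrics

TMB divides the count of missense calls at VAF ≥ 5% (inclusive) by the
non-overlapping target length: 3,040,053 bp for the gene panel, 38,289,292 bp
for the exome. The actionability cutoff is TMB ≥ 5 (inclusive by default; a
strict `> 5` mode exists because the two are used interchangeably in clinical
summaries). MSI-high is a pure threshold call (score ≥ 10) on a precomputed
score — locus-level MSI analysis is out of scope.

## Expression analysis

The low-count rule drops a gene iff its count fails to reach 20 in **every**
sample (max < 20); the alternative any-sample reading would discard most of
the transcriptome and is available as `mode="sum"`/toggles. Library sizes are
computed **after** gene filtering (fixed pipeline order), CPM columns sum to
10⁶ by construction, and log2 uses pseudocount 1 (configurable; no value is
canonical).

Two z-score orientations exist because "the Z-score of the log2 CPM values
for each sample" is ambiguous: `per_sample` standardizes within a sample
across genes (literal reading), `per_gene` standardizes a gene across the
cohort (what a sample-specific over-expression call needs). Both are
implemented and tested; the end-to-end pipeline uses `per_gene` over the
origin-tumor cohort for outlier calling, because a per-sample z-score cannot
distinguish a gene that is high in *this* tumor from one that is high in
every tumor. Note the finite-sample cap on a per-gene z-score, max
z = (n−1)/√n: calling at z ≥ 3 needs at least 11 samples, which the default
cohort (19 tumors) comfortably exceeds.

For model stages (P1/P2/P2-3D), outlier preservation is scored with a
reference z-score: the gene's mean and SD come from the origin-tumor cohort
and each model sample is scored against them. This keeps model samples from
diluting the standardization while asking the right question — does the model
still over-express what the tumor over-expressed?

Outlier-set preservation uses the hypergeometric upper tail
P[X ≥ overlap] with X ~ Hypergeom(universe, |A|, |B|), computed with scipy.

## Actionability grading

Evidence is encoded per drug record (`validated_direct` vs
`pathway_predicted`, `approved` vs `investigational`), which makes grading
deterministic: VERY_HIGH iff a surviving record is `validated_direct`, else
HIGH. Mechanism concordance drops inhibitor/antagonist records for
loss-of-function alterations in tumor suppressors; gain-of-function
alterations in oncogenes keep them. Alterations of unknown functional
direction keep their records but are capped at HIGH — grading an alteration
VERY_HIGH requires knowing the drug can act on it, which is a design choice
here, not an established convention. Functional direction comes from the
`effect` annotation when present; otherwise frameshift/stopgain default to
LOF and everything else stays unknown (missense is only GOF when
hotspot-flagged upstream). Hypermutation and MSI-high events carry the
knowledge base's immune-checkpoint records and grade VERY_HIGH.

Composition percentages (event-class breakdown) use largest-remainder
apportionment (ties to the larger count), which sums to exactly 100 and
matches how clinical summaries print such breakdowns; standalone fractions
use half-up rounding, and the germline carrier rate is reported to one
truncated decimal, the convention for that figure.

The packaged knowledge base (~47 genes, ≥ 1 drug record each) covers the
recurrently targetable neuroblastoma genes (ALK, MYCN, ATRX, MDM2, CDK4/6,
CCND1, PIK3CA, CDKN2A/B, HIF1A, TOP2A, …) plus predisposition genes (MITF,
TSHR, ATM, BRCA1/2, …). It is a curated fixture standing in for live
CIViC/OncoKB/DGIdb/TTD queries; the pseudo-target symbol `IMMUNE_CHECKPOINT`
keys the checkpoint-inhibitor records so the referential invariant (every
drug's gene exists) holds.

## Model fidelity

The VAF matrix takes the union of variant keys across samples and zero-fills
absences — correlation/PCA need a complete matrix, and "not called" is
closest to 0 VAF in bulk data; a missing-aware mode exists for sensitivity
checks. Correlation/clustering/PCA run on all calls; conserved-variant counts
use the rare (popmax ≤ 1%) + missense sets, mirroring how the two analyses
are used downstream. PCA mean-centers but does not rescale features (VAFs
share a scale). Constant columns are dropped with a notice; an all-constant
matrix is a degenerate-input error.

The Mann–Whitney test enumerates all C(n_a+n_b, n_a) rank assignments
(midranks for ties) when the pooled size is ≤ 20 — exact even under ties —
and otherwise uses the tie- and continuity-corrected normal approximation.
Stage comparisons pool variant-level VAFs across patients, matching how
per-stage distributions are summarized; tracked actionable events record an
absent stage value as missing, never 0.

## Synthetic cohort generator

The generator's defaults are the study conditions the analysis expects:

| parameter | default | rationale |
|---|---|---|
| `n_patients` / lineages / 3D | 19 / 5 / 4 | cohort design: 19 relapsed tumors, 5 engrafted to P2, 4 with spheres |
| `p1_variant_loss_rate` | 0.20 | ≥ 77–84% of variants conserved across murine passages (lower bounds) |
| `p2_additional_loss_rate` | 0.05 | second passage loses little on top of the first |
| `p3d_loss_rate` | 0.30 | ≥ 52% conserved in spheres vs P2 (lower bound) |
| `vaf_inflation_p1` | 1.3 | VAF medians rise sharply into mice (higher tumor purity) |
| `vaf_inflation_p2` | 1.05 | P1→P2 shift is much smaller |
| `vaf_deflation_3d` | 0.7 | VAFs fall in 3D spheres vs P2 |
| `vaf_jitter_sd` | 0.02 | small per-variant measurement noise |
| `variant_gain_rate` | 0.05 | new variants per passage; not quantified anywhere, chosen small |
| `outlier_fold_change` | 16 | planted over-expression, well above the ≥ 8× detectability floor |
| `hypermutator_flag_probability` | 0.05 | ~1 hypermutated tumor per 19 |
| `germline_carrier_probability` | 0.12 | ~2 carriers per 17 patients with normals |
| background VAFs | Beta(2,5) ≥ 0.05 | right-skewed clonal VAFs; no published distribution to copy |

Drift is multiplicative with Gaussian jitter, clipped to [0,1]; losses are
per-variant Bernoulli draws. Planted actionable lesions are exempt from loss,
mirroring the observed full conservation of actionable alterations across
generations — so lesion-tracking tests have deterministic ground truth while
background variants drift stochastically. Background variants are drawn in
fixed category proportions (caller-failed 5%, segdup 5%, common polymorphism
10%, off-target 5%, synonymous 15%, low-support 5%, sub-threshold VAF 10%,
remainder fully passing) so every filtration rule sees both passing and
failing exemplars. A hypermutator sample is planted by replaying the somatic
filter and adding exactly enough passing missense calls to cross the TMB
cutoff on the exome assay; this presumes the non-hypermutated background
stays below ~190 qualifying missense calls, true at the default 200
background variants (neuroblastoma is a low-TMB entity).

Expression counts are Poisson draws around a per-gene log2 baseline
(N(5, 2); 10% of genes drawn low to exercise the count filter) plus a shared
per-patient effect (N(0, 0.4), which makes within-lineage correlation exceed
between-lineage correlation) and per-sample noise (N(0, 0.2)). Outlier target
genes — the druggable oncogenes a planted lesion can land on — use a
moderate, well-expressed baseline (N(6, 1), never low-count), reflecting that
constitutively silent genes are not what over-expression screens call;
planted genes are assigned without replacement across patients while the
22-gene pool lasts, and the fold change applies in every stage sample of the
carrying patient (outlier lesions are conserved across a lineage).

The truth ledger records every planted lesion with its expected priority
(computed by replaying the grading rules at planting time, so ledger and
grader cannot drift apart) and every per-variant drift event
(retained/lost/gained with VAFs). Identical config ⇒ byte-identical outputs;
`Cohort.checksum()` hashes a canonical serialization for determinism checks.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
threshold-straddling annotation values, binomial variant loss, multiplicative
VAF drift, lineage-correlated expression with planted outliers. It does not
model read-level error, mutational signatures, subclonal phylogenies,
mouse-read contamination, or purity/ploidy effects on copy number — so green
tests demonstrate that the rules are implemented faithfully and recover known
ground truth under the stated model, not that the thresholds are optimal for
any particular real cohort.

## Problem sizes

Tests run on compact cohorts (6–20 patients, 60–500 background variants per
tumor, 120–1000 genes); the acceptance script uses the full default
configuration (19 patients, 200 background variants, 1000 genes), which
simulates and analyzes in a few seconds. These sizes were chosen as the
smallest at which every statistical property under test is comfortably
powered (e.g. per-gene outlier calling at z ≥ 3 needs > 11 samples; the
binomial conservation check uses 20 × 500 draws for a tight standard error).

## Known limitations

* The knowledge base is a static fixture; real deployments would regenerate
  it from CIViC/OncoKB/DGIdb/TTD snapshots and re-validate the closed
  vocabularies.
* "Focality" of amplifications is not re-derived from segment length; CN ≥ 10
  is the operative criterion (an optional max-length guard exists, default
  off). Copy number is consumed as given, with no purity correction.
* IGV review status is an upstream-supplied flag (`not_reviewed` treated as
  passed by default): manual inspection cannot be automated faithfully.
* The per-sample z-score orientation and the zero-fill convention for absent
  VAFs are stated defaults, not claims about what any particular study did;
  both have explicit alternatives.
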