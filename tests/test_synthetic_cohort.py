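"""Generator determinism, truth-ledger completeness, drift realism."""

import numpy as np
import pytest

from nbprecision import SimulationConfig, simulate_cohort, simulate_expression
from nbprecision.synthetic_cohort import ConfigurationError
from nbprecision.variant_filters import filter_somatic, prioritize_pathogenic


def tiny_config(**overrides) -> SimulationConfig:
    base = dict(seed=1, n_patients=6, n_lineage_patients=3, n_3d_patients=2,
                n_background_variants_per_tumor=60, n_genes_expression=120)
    base.update(overrides)
    return SimulationConfig(**base)


def test_determinism_same_seed():
    c1 = simulate_cohort(tiny_config())
    c2 = simulate_cohort(tiny_config())
    assert c1.checksum() == c2.checksum()
    assert simulate_cohort(tiny_config(seed=2)).checksum() != c1.checksum()


def test_zero_loss_gives_full_conservation():
    cfg = tiny_config(p1_variant_loss_rate=0.0, variant_gain_rate=0.0)
    cohort = simulate_cohort(cfg)
    for lin in cohort.lineages:
        pz = {v.key for v in lin.variants["PZ"]}
        p1 = {v.key for v in lin.variants["P1"]}
        assert pz <= p1 and pz == p1


def test_loss_rate_binomial_recovery():
    """Conserved fraction within 3 SE of 1 - loss over 20 x 500-variant lineages."""
    cfg = SimulationConfig(
        seed=5, n_patients=20, n_lineage_patients=20, n_3d_patients=0,
        n_background_variants_per_tumor=500, planted_actionable_snvs_per_tumor=0,
        planted_outlier_genes_per_sample=0, hypermutator_flag_probability=0.0,
        p1_variant_loss_rate=0.2, n_genes_expression=50,
    )
    cohort = simulate_cohort(cfg)
    fracs = []
    for lin in cohort.lineages:
        pz = {v.key for v in lin.variants["PZ"]}
        p1 = {v.key for v in lin.variants["P1"]}
        fracs.append(len(pz & p1) / len(pz))
    se = np.sqrt(0.2 * 0.8 / 500) / np.sqrt(20)
    assert abs(np.mean(fracs) - 0.8) <= 3 * se


def test_truth_ledger_planted_lesions_unique_and_rule_consistent():
    cohort = simulate_cohort(tiny_config(seed=3))
    t = cohort.truth
    snvs = t[t.kind == "planted_snv"]
    # exactly once per planted lesion
    assert not snvs.duplicated(subset=["sample_id", "chrom", "pos", "ref", "alt"]).any()
    # replaying the filtration rules on planted lesions keeps all of them
    for r in snvs.itertuples():
        sample_calls = cohort.variants[r.sample_id]
        planted = [v for v in sample_calls
                   if v.key == (r.chrom, r.pos, r.ref, r.alt)]
        assert len(planted) == 1
        kept, _ = filter_somatic(planted)
        assert prioritize_pathogenic(kept) == kept and len(kept) == 1
    cnvs = t[t.kind == "planted_cnv"]
    for r in cnvs.itertuples():
        genes = {g for s in cohort.cnvs[r.sample_id] for g in s.genes}
        assert r.gene in genes


def test_drift_median_increases_with_inflation():
    cohort = simulate_cohort(tiny_config(seed=9, vaf_inflation_p1=1.3))
    pz = [v.vaf for lin in cohort.lineages for v in lin.variants["PZ"]]
    p1 = [v.vaf for lin in cohort.lineages for v in lin.variants["P1"]]
    assert np.median(p1) >= np.median(pz)


def test_vaf_bounds_preserved_under_drift():
    cohort = simulate_cohort(tiny_config(seed=11, vaf_inflation_p1=3.0,
                                         vaf_jitter_sd=0.1))
    for sid, calls in cohort.variants.items():
        for v in calls:
            assert 0.0 <= v.vaf <= 1.0


def test_config_validation_names_field():
    with pytest.raises(ConfigurationError, match="p1_variant_loss_rate"):
        SimulationConfig(p1_variant_loss_rate=1.5)
    with pytest.raises(ConfigurationError, match="n_patients"):
        SimulationConfig(n_patients=-1)
    with pytest.raises(ConfigurationError, match="vaf_inflation_p1"):
        SimulationConfig(vaf_inflation_p1=0)
    with pytest.raises(ConfigurationError, match="n_3d_patients"):
        SimulationConfig(n_lineage_patients=2, n_3d_patients=3)


def test_config_yaml_roundtrip_rejects_unknown_keys():
    cfg = tiny_config()
    text = cfg.to_yaml()
    assert SimulationConfig.from_yaml(text) == cfg
    with pytest.raises(ConfigurationError, match="unknown"):
        SimulationConfig.from_yaml(text + "bogus_key: 1\n")


def test_expression_fold_change_one_plants_nothing():
    cfg = tiny_config(outlier_fold_change=1.0)
    cohort = simulate_cohort(cfg)
    assert (cohort.truth.kind == "planted_outlier").sum() == 0


def test_expression_ledger_bookkeeping():
    cohort = simulate_cohort(tiny_config(seed=17))
    t = cohort.truth
    planted = t[(t.kind == "planted_outlier") & (t.stage == "PZ")]
    assert len(planted) == len(cohort.tumor_samples)  # one per tumor sample
    for r in planted.itertuples():
        assert r.gene in cohort.expression.index
        assert r.sample_id in cohort.expression.columns


def test_within_lineage_correlation_exceeds_between():
    """Spearman correlation within a lineage beats between, over 10 seeds."""
    wins = 0
    for seed in range(10):
        cfg = SimulationConfig(
            seed=seed + 200, n_patients=4, n_lineage_patients=4, n_3d_patients=0,
            n_background_variants_per_tumor=10, planted_actionable_snvs_per_tumor=0,
            planted_outlier_genes_per_sample=0, n_genes_expression=150,
        )
        cohort = simulate_cohort(cfg)
        corr = cohort.expression.corr(method="spearman")
        within, between = [], []
        sids = {lin.patient_id: [lin.sample_ids[s] for s in lin.stages]
                for lin in cohort.lineages}
        for pid, ss in sids.items():
            for i, a in enumerate(ss):
                for b in ss[i + 1:]:
                    within.append(corr.loc[a, b])
            for qid, tt in sids.items():
                if qid <= pid:
                    continue
                for a in ss:
                    for b in tt:
                        between.append(corr.loc[a, b])
        if np.mean(within) > np.mean(between):
            wins += 1
    assert wins == 10


def test_expression_minimum_gene_count():
    with pytest.raises(ConfigurationError, match="n_genes_expression"):
        simulate_expression(SimulationConfig(seed=1, n_genes_expression=49), [])


def test_hypermutator_crosses_tmb_cutoff():
    from nbprecision.burden_metrics import compute_tmb

    cfg = tiny_config(seed=23, hypermutator_flag_probability=1.0, n_patients=3,
                      n_lineage_patients=0, n_3d_patients=0)
    cohort = simulate_cohort(cfg)
    for sid in cohort.tumor_samples:
        kept, _ = filter_somatic(cohort.variants[sid])
        res = compute_tmb(kept, target_length_bp=cfg.exome_length_bp)
        assert res.actionable
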