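"""VAF matrices, similarity suite, conservation counts, Mann-Whitney shifts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from nbprecision import SimulationConfig, simulate_cohort
from nbprecision.model_fidelity import (
    LineageSet,
    build_vaf_matrix,
    conserved_fraction,
    similarity_suite,
    track_actionable,
    vaf_shift_test,
)

from conftest import make_variant


def test_vaf_matrix_forced_construction():
    a = make_variant(chrom="chr1", pos=100, vaf=0.4, alt_reads=80, depth=200)
    b = make_variant(chrom="chr2", pos=200, vaf=0.5, alt_reads=100, depth=200)
    m = build_vaf_matrix({"A": [a], "B": [b]})
    assert m.shape == (2, 2)
    assert m.loc["A"].tolist() == [0.4, 0.0]
    assert m.loc["B"].tolist() == [0.0, 0.5]
    # identical call sets give identical rows
    m2 = build_vaf_matrix({"A": [a, b], "B": [a, b]})
    assert (m2.loc["A"] == m2.loc["B"]).all()


def test_vaf_matrix_duplicate_key_rejected():
    v = make_variant()
    with pytest.raises(ValueError, match="duplicate"):
        build_vaf_matrix({"A": [v, v], "B": [v]})


def test_vaf_matrix_lookup_oracle():
    rng = np.random.default_rng(8)
    per_sample = {}
    for s in ["S1", "S2", "S3"]:
        calls = []
        for i in range(40):
            if rng.random() < 0.6:
                vaf = float(rng.uniform(0.05, 0.9))
                depth = 200
                alt = round(vaf * depth)
                calls.append(make_variant(chrom="chr1", pos=1000 + i, vaf=alt / depth,
                                          alt_reads=alt, depth=depth, sample_id=s))
        per_sample[s] = calls
    m = build_vaf_matrix(per_sample, zero_fill=True)
    for s, calls in per_sample.items():
        lookup = {f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}": v.vaf for v in calls}
        for col in m.columns:
            assert m.loc[s, col] == lookup.get(col, 0.0)


def test_similarity_duplicated_samples():
    rng = np.random.default_rng(1)
    row = rng.uniform(0, 1, size=30)
    other = rng.uniform(0, 1, size=30)
    m = pd.DataFrame([row, row, other], index=["dup1", "dup2", "far"])
    res = similarity_suite(m)
    assert res.correlation.loc["dup1", "dup2"] == pytest.approx(1.0)
    # symmetric, unit diagonal
    assert np.allclose(res.correlation, res.correlation.T)
    assert np.allclose(np.diag(res.correlation), 1.0)
    # the duplicated pair merges first, at height 0
    assert res.linkage[0, 2] == pytest.approx(0.0)
    assert set(res.linkage[0, :2].astype(int)) == {0, 1}
    # identical PCA coordinates for duplicates
    assert np.allclose(res.pca_coords.loc["dup1"], res.pca_coords.loc["dup2"])
    assert res.explained_variance.sum() <= 1 + 1e-9


def test_ward_merge_heights_lance_williams():
    """3-sample toy: Ward heights via the Lance-Williams recurrence by hand."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
    m = pd.DataFrame(pts, index=["a", "b", "c"])
    res = similarity_suite(m)
    # first merge: a,b at Euclidean distance 1
    assert res.linkage[0, 2] == pytest.approx(1.0)
    # Lance-Williams (Ward): d({a,b},c)^2 = (2/3)d(a,c)^2 + (2/3)d(b,c)^2 - (1/3)d(a,b)^2
    d_ab, d_ac, d_bc = 1.0, 5.0, 4.0
    expected = math.sqrt((2 * d_ac**2 + 2 * d_bc**2 - d_ab**2) / 3)
    assert res.linkage[1, 2] == pytest.approx(expected)


def test_similarity_constant_features_and_degenerate_input():
    m = pd.DataFrame([[0.5, 0.1, 0.3], [0.5, 0.4, 0.2]], index=["A", "B"])
    res = similarity_suite(m)
    assert res.dropped_features == [0]
    with pytest.raises(ValueError, match="constant"):
        similarity_suite(pd.DataFrame([[1.0, 1.0], [1.0, 1.0]]))
    with pytest.raises(ValueError):
        similarity_suite(m, corr_method="kendall")


def test_similarity_permutation_invariance():
    rng = np.random.default_rng(5)
    m = pd.DataFrame(rng.uniform(0, 1, size=(5, 20)),
                     index=[f"S{i}" for i in range(5)])
    res = similarity_suite(m)
    perm = m.iloc[[3, 1, 4, 0, 2]]
    res_p = similarity_suite(perm)
    for i in m.index:
        for j in m.index:
            assert res.correlation.loc[i, j] == pytest.approx(res_p.correlation.loc[i, j])
    assert np.allclose(np.sort(res.linkage[:, 2]), np.sort(res_p.linkage[:, 2]))


def test_two_lineage_clustering_recovery():
    """Ward clustering separates two simulated lineages, 10/10 seeds."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        center_a = rng.uniform(0.1, 0.9, size=50)
        center_b = rng.uniform(0.1, 0.9, size=50)
        rows, labels = [], []
        for i in range(5):
            rows.append(np.clip(center_a + rng.normal(0, 0.02, 50), 0, 1))
            labels.append("A")
        for i in range(5):
            rows.append(np.clip(center_b + rng.normal(0, 0.02, 50), 0, 1))
            labels.append("B")
        m = pd.DataFrame(rows, index=[f"{l}{i}" for i, l in enumerate(labels)])
        res = similarity_suite(m)
        cut = hierarchy.fcluster(res.linkage, t=2, criterion="maxclust")
        groups = {}
        for lab, cl in zip(labels, cut):
            groups.setdefault(cl, set()).add(lab)
        assert sorted(map(tuple, groups.values())) == [("A",), ("B",)]


def test_conserved_fraction_cases():
    a = [("chr1", 1, "A", "T"), ("chr1", 2, "A", "T"), ("chr1", 3, "A", "T")]
    b = [("chr1", 1, "A", "T"), ("chr1", 2, "A", "T"), ("chr1", 4, "A", "T")]
    shared, frac = conserved_fraction(a, b)
    assert (shared, frac) == (2, pytest.approx(2 / 3))
    assert conserved_fraction(a, a) == (3, 1.0)
    assert conserved_fraction(a, []) == (0, 0.0)
    assert conserved_fraction([], a) == (0, None)


def test_conserved_fraction_binomial_oracle():
    """Mean conserved fraction within 3 SE of 1 - loss rate (20 replicates x 500)."""
    cfg = SimulationConfig(
        seed=13, n_patients=20, n_lineage_patients=20, n_3d_patients=0,
        n_background_variants_per_tumor=500, planted_actionable_snvs_per_tumor=0,
        planted_outlier_genes_per_sample=0, hypermutator_flag_probability=0.0,
        p1_variant_loss_rate=0.2, n_genes_expression=50,
    )
    cohort = simulate_cohort(cfg)
    fracs = []
    for lin in cohort.lineages:
        _, frac = conserved_fraction(lin.variants["PZ"], lin.variants["P1"])
        fracs.append(frac)
    assert len(fracs) == 20
    se = math.sqrt(0.2 * 0.8 / 500) / math.sqrt(20)
    assert abs(np.mean(fracs) - 0.8) <= 3 * se


def test_mannwhitney_identical_groups_exact_p1():
    res = vaf_shift_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
    assert res.method == "exact"
    assert res.p_value == pytest.approx(1.0)


def test_mannwhitney_exact_enumeration_oracle():
    a, b = [0.1, 0.2, 0.3], [0.4, 0.5, 0.6]
    res = vaf_shift_test(a, b)
    # independent enumeration over all C(6,3)=20 rank assignments
    pooled = stats.rankdata(a + b)
    mu = 4.5
    obs = sum(pooled[:3]) - 6
    count = sum(
        1 for idx in itertools.combinations(range(6), 3)
        if abs(sum(pooled[i] for i in idx) - 6 - mu) >= abs(obs - mu) - 1e-12
    )
    assert res.u_statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(count / 20) == pytest.approx(0.1)
    # cross-check against the library's exact method (tie-free case)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert res.p_value == pytest.approx(ref.pvalue)


def test_mannwhitney_detects_inflation():
    """Simulated 1.3x VAF inflation detected at p < 0.01 in >= 9/10 seeds."""
    detected = 0
    for seed in range(10):
        cfg = SimulationConfig(
            seed=seed + 100, n_patients=1, n_lineage_patients=1, n_3d_patients=0,
            n_background_variants_per_tumor=500, planted_actionable_snvs_per_tumor=0,
            planted_outlier_genes_per_sample=0, hypermutator_flag_probability=0.0,
            p1_variant_loss_rate=0.0, variant_gain_rate=0.0,
            vaf_inflation_p1=1.3, n_genes_expression=50,
        )
        lin = simulate_cohort(cfg).lineages[0]
        res = vaf_shift_test([v.vaf for v in lin.variants["PZ"]],
                             [v.vaf for v in lin.variants["P1"]])
        if res.p_value < 0.01 and res.median_b > res.median_a:
            detected += 1
    assert detected >= 9


def test_mannwhitney_empty_group_rejected():
    with pytest.raises(ValueError):
        vaf_shift_test([], [0.1])


def test_track_actionable_missing_is_none_not_zero(kb):
    from nbprecision.actionability import ActionableEvent

    v_pz = make_variant(chrom="chr3", pos=500, vaf=0.4, alt_reads=80, depth=200)
    lin = LineageSet(
        patient_id="Pz01",
        variants={"PZ": [v_pz], "P1": []},  # lost at P1
    )
    ev = ActionableEvent(
        patient_id="Pz01", sample_id="Pz01", event_class="SNV_INDEL", gene="ALK",
        pathway="", priority="VERY_HIGH", drugs=kb.drugs_for("ALK"),
        detail={"key": v_pz.key},
    )
    traj = track_actionable([ev], lin)
    assert traj.loc[0, "value_PZ"] == pytest.approx(0.4)
    assert traj.loc[0, "value_P1"] is None


def test_track_actionable_no_loss_inflation_monotone(kb):
    """With zero loss, zero jitter and inflation 1.2, VAF(P1) >= VAF(PZ)."""
    cfg = SimulationConfig(
        seed=21, n_patients=2, n_lineage_patients=2, n_3d_patients=0,
        n_background_variants_per_tumor=50, planted_actionable_snvs_per_tumor=2,
        p1_variant_loss_rate=0.0, p2_additional_loss_rate=0.0,
        vaf_inflation_p1=1.2, vaf_jitter_sd=0.0, variant_gain_rate=0.0,
        n_genes_expression=50, planted_outlier_genes_per_sample=0,
        hypermutator_flag_probability=0.0,
    )
    cohort = simulate_cohort(cfg)
    from nbprecision import run_pipeline

    result = run_pipeline(cohort)
    traj = result.fidelity.trajectories
    snv = traj[traj.event_class == "SNV_INDEL"].dropna(subset=["value_PZ", "value_P1"])
    assert len(snv) > 0
    assert (snv["value_P1"] >= snv["value_PZ"] - 1e-9).all()


def test_track_actionable_cnv_trajectory(kb):
    from nbprecision.actionability import ActionableEvent
    from nbprecision.cnv_selection import CnvSegment

    seg_pz = CnvSegment(chrom="chr2", start=100, end=200, copy_number=12,
                        genes=("MYCN",), sample_id="Pz01")
    seg_p1 = CnvSegment(chrom="chr2", start=100, end=200, copy_number=14,
                        genes=("MYCN",), sample_id="Pz01-P1")
    lin = LineageSet(patient_id="Pz01",
                     variants={"PZ": [], "P1": []},
                     cnvs={"PZ": [seg_pz], "P1": [seg_p1]})
    ev = ActionableEvent(patient_id="Pz01", sample_id="Pz01", event_class="CNV",
                         gene="MYCN", pathway="", priority="VERY_HIGH",
                         drugs=kb.drugs_for("MYCN"), detail={"kind": "amplification"})
    traj = track_actionable([ev], lin)
    assert traj.loc[0, "value_PZ"] == 12 and traj.loc[0, "value_P1"] == 14
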