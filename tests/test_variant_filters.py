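"""Filtration cascades: rule attribution, boundaries, oracle equivalence."""

import numpy as np
import pytest

from nbprecision.variant_filters import (
    SmallVariant,
    VariantInputError,
    filter_germline,
    filter_somatic,
    filter_tumor_only,
    prioritize_pathogenic,
)

from conftest import make_variant, random_variants


def somatic_predicate(v, maf=0.01, min_alt=8, min_vaf=0.05):
    """Independent per-record re-check of the somatic rules."""
    return (
        v.caller_pass
        and not v.in_segdup
        and (v.popmax_af is None or v.popmax_af <= maf)
        and v.on_target
        and v.consequence != "synonymous"
        and v.alt_reads >= min_alt
        and v.vaf >= min_vaf
    )


@pytest.mark.parametrize(
    "overrides,rule",
    [
        (dict(caller_pass=False), "caller_fail"),
        (dict(in_segdup=True), "segdup"),
        (dict(popmax_af=0.02), "common_polymorphism"),
        (dict(on_target=False), "off_target"),
        (dict(consequence="synonymous"), "synonymous"),
        (dict(alt_reads=7, vaf=0.20, depth=35), "read_support"),
        (dict(vaf=0.03, alt_reads=12, depth=400), "low_vaf"),
    ],
)
def test_somatic_single_rule_attribution(overrides, rule):
    v = make_variant(**overrides)
    kept, audit = filter_somatic([v])
    assert kept == []
    assert audit.removed_by_rule[rule] == 1
    assert sum(audit.removed_by_rule.values()) == 1


def test_somatic_boundaries():
    # popmax exactly at the cutoff is kept (removal is strict > 1%)
    kept, _ = filter_somatic([make_variant(popmax_af=0.01)])
    assert len(kept) == 1
    # both read-support requirements are inclusive at their thresholds
    kept, _ = filter_somatic([make_variant(alt_reads=8, depth=160, vaf=0.05)])
    assert len(kept) == 1


def test_somatic_planted_batch_matches_plan():
    passing = [make_variant(pos=1_400_000 + i) for i in range(10)]
    violations = [
        make_variant(pos=1, caller_pass=False),
        make_variant(pos=2, in_segdup=True),
        make_variant(pos=3, popmax_af=0.05),
        make_variant(pos=4, on_target=False),
        make_variant(pos=5, consequence="synonymous"),
        make_variant(pos=6, alt_reads=3, vaf=0.3, depth=10),
    ]
    kept, audit = filter_somatic(passing + violations)
    assert len(kept) == 10
    assert audit.input_count == 16
    expected = dict(caller_fail=1, segdup=1, common_polymorphism=1,
                    off_target=1, synonymous=1, read_support=1, low_vaf=0)
    assert dict(audit.removed_by_rule) == expected


def test_somatic_oracle_equivalence_and_conservation():
    rng = np.random.default_rng(11)
    batch = random_variants(rng, 1000)
    kept, audit = filter_somatic(batch)
    expected = [v for v in batch if somatic_predicate(v)]
    assert [v.key for v in kept] == [v.key for v in expected]
    assert audit.kept_count + sum(audit.removed_by_rule.values()) == audit.input_count


def test_somatic_order_independence_and_idempotence():
    rng = np.random.default_rng(3)
    batch = random_variants(rng, 400)
    kept, _ = filter_somatic(batch)
    # membership equals the intersection of single-rule kept sets
    singles = [
        {v.key for v in batch if v.caller_pass},
        {v.key for v in batch if not v.in_segdup},
        {v.key for v in batch if v.popmax_af is None or v.popmax_af <= 0.01},
        {v.key for v in batch if v.on_target},
        {v.key for v in batch if v.consequence != "synonymous"},
        {v.key for v in batch if v.alt_reads >= 8},
        {v.key for v in batch if v.vaf >= 0.05},
    ]
    assert {v.key for v in kept} == set.intersection(*singles)
    # idempotence: a second pass removes nothing
    kept2, audit2 = filter_somatic(kept)
    assert [v.key for v in kept2] == [v.key for v in kept]
    assert sum(audit2.removed_by_rule.values()) == 0


def test_prioritize_boundaries_and_oracle():
    assert prioritize_pathogenic([make_variant(cadd_phred=21.0, cancervar_score=None)])
    # strict inequalities: exactly at both cutoffs fails
    assert not prioritize_pathogenic(
        [make_variant(cadd_phred=20.0, cancervar_score=0.80)]
    )
    assert prioritize_pathogenic([make_variant(cadd_phred=None, cancervar_score=0.81)])
    rng = np.random.default_rng(5)
    batch = random_variants(rng, 1000)
    got = {v.key for v in prioritize_pathogenic(batch)}
    want = {
        v.key for v in batch
        if (v.cadd_phred is not None and v.cadd_phred > 20)
        or (v.cancervar_score is not None and v.cancervar_score > 0.80)
    }
    assert got == want


def test_tumor_only_cosmic_rescue_and_strict_mode():
    common_cosmic = make_variant(popmax_af=0.01, in_cosmic=True)
    common_not = make_variant(pos=1_400_001, popmax_af=0.01, in_cosmic=False)
    rare = make_variant(pos=1_400_002, popmax_af=0.0005, in_cosmic=False)
    kept, audit = filter_tumor_only([common_cosmic, common_not, rare])
    assert {v.pos for v in kept} == {1_500_000, 1_400_002}
    assert audit.removed_by_rule["tumor_only_popmax"] == 1
    kept_strict, _ = filter_tumor_only(
        [common_cosmic, common_not, rare], cosmic_rescue=False
    )
    assert {v.pos for v in kept_strict} == {1_400_002}


def test_tumor_only_applies_somatic_rules_first():
    v = make_variant(consequence="synonymous", popmax_af=0.01, in_cosmic=True)
    kept, audit = filter_tumor_only([v])
    assert kept == []
    assert audit.removed_by_rule["synonymous"] == 1


def test_germline_rules():
    genes = {"MITF", "TSHR", "BRCA1"}
    carrier = make_variant(gene="MITF", clinvar_class="Pathogenic", vaf=0.5,
                           alt_reads=100, depth=200)
    conflicting = make_variant(pos=1_400_003, gene="TSHR",
                               clinvar_class="Conflicting",
                               intervar_class="Pathogenic", vaf=0.5,
                               alt_reads=100, depth=200)
    off_list = make_variant(pos=1_400_004, gene="ALK",
                            clinvar_class="Pathogenic", vaf=0.5,
                            alt_reads=100, depth=200)
    intervar_only = make_variant(pos=1_400_005, gene="BRCA1",
                                 clinvar_class="VUS",
                                 intervar_class="Likely_pathogenic", vaf=0.5,
                                 alt_reads=100, depth=200)
    kept, _ = filter_germline([carrier, conflicting, off_list, intervar_only], genes)
    assert {v.gene for v in kept} == {"MITF", "BRCA1"}
    with pytest.raises(ValueError):
        filter_germline([carrier], [])


def test_germline_keeps_synonymous_rule_out():
    # the synonymous exclusion is somatic-specific and must not apply here
    v = make_variant(gene="MITF", consequence="synonymous",
                     clinvar_class="Pathogenic", vaf=0.5, alt_reads=100, depth=200)
    kept, _ = filter_germline([v], {"MITF"})
    assert len(kept) == 1


def test_invalid_records_raise():
    with pytest.raises(VariantInputError):
        SmallVariant(chrom="", pos=1, ref="A", alt="T", vaf=0.5)
    with pytest.raises(VariantInputError):
        make_variant(vaf=1.5)
    with pytest.raises(VariantInputError):
        make_variant(alt_reads=300, depth=200)
    with pytest.raises(VariantInputError):
        make_variant(consequence="nonsense_vocab")
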