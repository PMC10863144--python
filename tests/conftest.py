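import numpy as np
import pytest

from nbprecision import KnowledgeBase, SimulationConfig, simulate_cohort
from nbprecision.variant_filters import SmallVariant


@pytest.fixture(scope="session")
def kb():
    return KnowledgeBase.load_default()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused by read-only tests."""
    cfg = SimulationConfig(
        seed=7, n_patients=12, n_background_variants_per_tumor=80, n_genes_expression=300
    )
    return simulate_cohort(cfg)


def make_variant(**overrides) -> SmallVariant:
    """A fully passing somatic missense call unless overridden."""
    base = dict(
        chrom="chr1", pos=1_500_000, ref="A", alt="T", vaf=0.30,
        sample_id="S1", gene="BGD00001", consequence="missense",
        caller_pass=True, popmax_af=None, cadd_phred=25.0, cancervar_score=None,
        in_cosmic=False, alt_reads=60, depth=200, in_segdup=False,
        on_target=True, effect="unknown",
    )
    base.update(overrides)
    return SmallVariant(**base)


@pytest.fixture
def variant_factory():
    return make_variant


def random_variants(rng: np.random.Generator, n: int) -> list[SmallVariant]:
    """Random batch exercising every filtration predicate independently."""
    out = []
    consequences = ["missense", "synonymous", "stopgain", "frameshift", "splice",
                    "inframe_indel", "other_exonic", "non_exonic"]
    clin = ["Pathogenic", "Likely_pathogenic", "Benign", "Likely_benign", "VUS",
            "Conflicting", None]
    for i in range(n):
        depth = int(rng.integers(20, 400))
        alt_reads = int(rng.integers(0, depth + 1))
        out.append(
            SmallVariant(
                chrom=f"chr{int(rng.integers(1, 23))}",
                pos=int(rng.integers(1, 5_000_000)) + i * 10_000_000,
                ref="A", alt="G",
                vaf=alt_reads / depth,
                sample_id="R",
                gene=str(rng.choice(["MITF", "TSHR", "ALK", "TP53", "BGDX"])),
                consequence=str(rng.choice(consequences)),
                caller_pass=bool(rng.random() < 0.8),
                popmax_af=None if rng.random() < 0.4 else float(rng.uniform(0, 0.05)),
                cadd_phred=None if rng.random() < 0.2 else float(rng.uniform(0, 45)),
                cancervar_score=None if rng.random() < 0.5 else float(rng.uniform(0, 1)),
                clinvar_class=clin[int(rng.integers(len(clin)))],
                intervar_class=clin[int(rng.integers(len(clin)))],
                in_cosmic=bool(rng.random() < 0.2),
                alt_reads=alt_reads, depth=depth,
                in_segdup=bool(rng.random() < 0.1),
                on_target=bool(rng.random() < 0.9),
            )
        )
    return out
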