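import numpy as np
import pytest

from cutscan.genome_scan import GuideTarget
from cutscan.synthetic_data import (
    SyntheticConfig,
    generate_reference,
    simulate_junctions,
)

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(BASES[c] for c in rng.integers(0, 4, n))


def mutate_protospacer(proto, k, rng):
    """Introduce exactly k substitutions at distinct positions."""
    s = list(proto)
    for p in rng.choice(len(s), size=k, replace=False):
        s[p] = BASES[(BASES.index(s[p]) + rng.integers(1, 4)) % 4]
    return "".join(s)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def guide():
    return GuideTarget(
        protospacer="GACGTTAACCGGATCGATCG",
        pam_pattern="NGG",
        chrom="chr1",
        protospacer_start=500,
        strand="+",
    )


@pytest.fixture
def small_config():
    return SyntheticConfig(
        genome_length=120_000,  # keeps the chr1 planted site outside the ±20 kb zone
        chrom_count=2,
        planted_sites=[
            (2, "AGG", "chr2", 5_000),
            (4, "TGA", "chr2", 20_000),
            (6, "CCT", "chr1", 1_000),
        ],
        outcome_proportions={
            "uncut": 0.4,
            "indel": 0.3,
            "large_deletion": 0.05,
            "offtarget_translocation": 0.2,
            "general_translocation": 0.003,
            "plasmid_insertion": 0.047,
        },
        n_events=3_000,
        seed=3,
    )


@pytest.fixture
def small_bundle(small_config):
    """Genome/plasmid/guide/truth plus a simulated junction table."""
    genome, plasmid, g, truth = generate_reference(small_config)
    table = simulate_junctions(truth, small_config)
    return {
        "config": small_config,
        "genome": genome,
        "plasmid": plasmid,
        "guide": g,
        "truth": truth,
        "junctions": table,
    }
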