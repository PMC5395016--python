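import numpy as np
import pytest

from refgrade.config import SimConfig
from refgrade.simulate import simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale study: 120 kb, one chromosome, reduced event counts."""
    return SimConfig(
        seed=5,
        genome_length=120_000,
        n_chromosomes=1,
        n_substitution_errors=12,
        n_insertion_errors=4,
        n_deletion_errors=4,
        n_between_sites=4,
        n_within_sites=4,
        n_genes=6,
        physical_gap_size=8_000,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_study(small_config, small_sim):
    from refgrade.pipeline import run_error_study

    return run_error_study(small_config, sim=small_sim)


def make_column(ref_base: str, base_counts: dict, chrom="chr01", pos=100):
    from refgrade.pileup import PileupColumn

    return PileupColumn(
        chrom, pos, ref_base, sum(base_counts.values()),
        {b: base_counts.get(b, 0) for b in "ACGTN"},
    )
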