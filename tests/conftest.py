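import numpy as np
import pytest

from concordkit.normalize import MatchConfig
from concordkit.synthdata import SimulationConfig, make_reference
from concordkit.variants import Reference


@pytest.fixture
def toy_ref():
    # homopolymer and dinucleotide context for normalization edge cases
    return Reference({
        "chr1": "GCAAAACTTTTGGACGTACGTAGAGAGAGCCCTA" * 3,
        "chr2": "ACGTACGTGGGGGGGGACGTACGTACGTTTTTTTACGT" * 3,
    })


@pytest.fixture
def match_cfg():
    return MatchConfig()


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated study shared by read-only tests."""
    from concordkit.synthdata import simulate_study

    cfg = SimulationConfig(seed=11, genome_length=200_000, n_chromosomes=2,
                           n_snv=800, n_indel=120)
    ref, truth, sims, platform = simulate_study(cfg)
    return cfg, ref, truth, sims, platform


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
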