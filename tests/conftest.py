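import pytest

from pyrodrift import (
    CommunitySpec, ConfusablePair, QualityFilterParams, SimParams,
    build_word_model, demultiplex, generate_reference_sequences,
    generate_taxonomy, simulate_amplicon_reads,
)
from pyrodrift.simulate import default_architecture


@pytest.fixture(scope="session")
def arch():
    return default_architecture()


@pytest.fixture(scope="session")
def community_spec():
    """32-genus community with a planted confusable genus pair."""
    return CommunitySpec(
        n_phyla=2, n_genera_per_path=2, confusable_pair=ConfusablePair(), seed=11,
    )


@pytest.fixture(scope="session")
def taxonomy(community_spec):
    return generate_taxonomy(community_spec)


@pytest.fixture(scope="session")
def refdb(taxonomy, arch, community_spec):
    return generate_reference_sequences(taxonomy, arch, community_spec)


@pytest.fixture(scope="session")
def word_model(refdb):
    return build_word_model(refdb)


@pytest.fixture(scope="session")
def clean_reads(refdb, arch):
    """Error-free full-length reads, 120 per sample, three samples."""
    sim = SimParams(
        n_reads=120, n_samples=3, length_mean=600.0, length_sd=0.0,
        substitution_rate=0.0, homopolymer_rate=0.0, seed=21,
    )
    return simulate_amplicon_reads(refdb, arch, sim), sim


@pytest.fixture(scope="session")
def noisy_reads(refdb, arch):
    """Reads with the default 454-like error model, one sample."""
    sim = SimParams(
        n_reads=150, n_samples=1, substitution_rate=0.005,
        homopolymer_rate=0.002, seed=22,
    )
    return simulate_amplicon_reads(refdb, arch, sim), sim


@pytest.fixture(scope="session")
def qparams():
    return QualityFilterParams()


@pytest.fixture(scope="session")
def sample1(clean_reads):
    reads, sim = clean_reads
    return demultiplex(reads, list(sim.mid_sequences))["S1"]
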