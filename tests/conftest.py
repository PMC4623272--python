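import pytest

from ere_scout import discovery, polymorph, synth

SMALL_CONFIG = synth.SimulationConfig(
    seed=11,
    genome_length=400_000,
    n_loci=40,
    n_het_loci=6,
    n_repeat_embedded=3,
    n_multicopy=2,
    n_decoy_repeats=8,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A 400 kb synthetic dataset shared across module tests."""
    return synth.simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_loci(small_dataset):
    ds = small_dataset
    return discovery.discover(
        ds.consensus,
        ds.contigs,
        discovery.PlacementTable(ds.placement),
        ds.repeats,
    )


@pytest.fixture(scope="session")
def small_calls(small_dataset, small_loci):
    ds = small_dataset
    return polymorph.find_heterozygous_loci(ds.chromosomes, small_loci, ds.traces)


@pytest.fixture(scope="session")
def consensus():
    return synth.generate_consensus(3, 225)
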