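import pytest
from hypothesis import settings

from isomirkit import assign, refdb, simdata

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

# fixed toy locus used throughout: 20 nt mature flanked by GGG / TCA
TOY_MATURE_SEQ = "ACGTACGTACGTACGTACGT"
TOY_FLANK5 = "GGG"
TOY_FLANK3 = "TCA"


@pytest.fixture(scope="session")
def toy_mature():
    return refdb.MatureRecord("hsa-test-5p", "MIMAT0000001", TOY_MATURE_SEQ)


@pytest.fixture(scope="session")
def toy_hairpin():
    return refdb.HairpinRecord("hsa-test-hp", TOY_FLANK5 + TOY_MATURE_SEQ + TOY_FLANK3)


@pytest.fixture(scope="session")
def toy_db(toy_mature, toy_hairpin):
    return refdb.build_database([toy_mature], [toy_hairpin])


@pytest.fixture(scope="session")
def sim_reference():
    """Seeded 5-locus synthetic reference shared across tests."""
    config = simdata.SimConfig(seed=7, n_loci=5)
    matures, hairpins, loci = simdata.make_toy_reference(config)
    return config, matures, hairpins, loci


@pytest.fixture(scope="session")
def sim_db(sim_reference):
    _, matures, hairpins, _ = sim_reference
    return refdb.build_database(matures, hairpins)


@pytest.fixture(scope="session")
def sim_index(sim_db):
    return assign.build_index(sim_db)
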