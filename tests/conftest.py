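import pytest

from mlstkit.scheme_db import (
    AlleleProfile,
    LocusAlleleSet,
    MLSTDatabase,
    ProfileTable,
    SchemeDefinition,
)
from mlstkit.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def toy_scheme() -> SchemeDefinition:
    return SchemeDefinition(name="TOY", loci=("aaa", "bbb"))


@pytest.fixture
def toy_db(toy_scheme) -> MLSTDatabase:
    """Two-locus database with two alleles per locus and one registered ST."""
    alleles = {
        "aaa": LocusAlleleSet(locus="aaa", alleles={1: "AAA", 2: "AAT"}),
        "bbb": LocusAlleleSet(locus="bbb", alleles={1: "CCC", 2: "CCG"}),
    }
    table = ProfileTable(scheme=toy_scheme)
    table.register(AlleleProfile.from_dict({"aaa": 1, "bbb": 1}, toy_scheme))
    return MLSTDatabase(scheme=toy_scheme, alleles=alleles, profiles=table)


@pytest.fixture(scope="session")
def study_sim():
    """The default study emulation (39 strains, 31 STs, 7-locus scheme), seed 1."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast population for pipeline-level tests."""
    cfg = SimulationConfig(
        seed=3,
        n_loci=3,
        locus_length=120,
        n_alleles_per_locus=4,
        n_strains=10,
        n_STs=6,
        flank_length=80,
        hut_knockout_fraction=0.2,
    )
    return simulate(cfg)
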