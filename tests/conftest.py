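import pytest

from dyadscout import (
    ColonyImplant,
    DyadImplant,
    FixtureSpec,
    GeneImplant,
    Motif,
    build_fixture,
    fit_lambda,
)

GGC = Motif("GGC")
GCC = Motif("GCC")


@pytest.fixture(scope="session")
def table1_model():
    """The published colony-size model: 26 kb window, 26,199 dyads, 3 Gb genome."""
    return fit_lambda(26_199, genome_size_bp=3e9, window_bp=26_000)


@pytest.fixture
def small_fixture():
    """One 20-kb chromosome: a 5-member GGC colony, a lone GCC triple run, a gene."""
    spec = FixtureSpec(
        chromosomes={"chr1": 20_000},
        seed=7,
        colony_implants=(ColonyImplant("chr1", 1_000, ("GGC",) * 5, gap=100),),
        dyad_implants=(DyadImplant("chr1", 15_000, "GCC", run_length=3),),
        gene_implants=(
            GeneImplant(
                "chr1",
                3_000,
                8_000,
                strand="+",
                gene_id="TESTG",
                exons=((3_000, 3_200), (7_800, 8_000)),
            ),
        ),
    )
    return spec, build_fixture(spec)
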