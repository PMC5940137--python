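import pytest

from modscreen.formats_io import GeneModel, GenomeSequence, StrainVariantSet, VariantCall
from modscreen.synthetic_data import ScreenSimConfig, ScreenSimulator


@pytest.fixture(scope="session")
def toy_gene():
    """Plus-strand single-exon gene with CDS ATG CAA GGA TAA at 101-112."""
    return GeneModel(
        gene_id="toy",
        contig="chrI",
        strand="+",
        cds_intervals=((101, 112),),
        gene_span=(101, 112),
    )


@pytest.fixture(scope="session")
def toy_genome(toy_gene):
    seq = ["A"] * 300
    seq[100:112] = list("ATGCAAGGATAA")
    return {"chrI": GenomeSequence("chrI", "".join(seq))}


@pytest.fixture(scope="session")
def sim():
    """Small deterministic simulated screen shared across tests."""
    simulator = ScreenSimulator(ScreenSimConfig(seed=42))
    simulator.simulate_genome()
    return simulator


@pytest.fixture(scope="session")
def sim_screen(sim):
    parental, strains, table, truth = sim.simulate_screen()
    return sim, parental, strains, table, truth


def make_set(strain_id, triples):
    """StrainVariantSet from (contig, pos, ref, alt) tuples."""
    return StrainVariantSet.from_calls(
        strain_id, [VariantCall(c, p, r, a) for c, p, r, a in triples]
    )
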