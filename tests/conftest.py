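import pytest

from linspec.lineage_classifier import classify_proteome
from linspec.synthetic_data import SimulationSpec, simulate_lineage_genomes


@pytest.fixture(scope="session")
def sim_spec() -> SimulationSpec:
    return SimulationSpec()


@pytest.fixture(scope="session")
def sim(sim_spec):
    """One 100-gene lineage simulation shared across the suite."""
    return simulate_lineage_genomes(sim_spec, seed=1)


@pytest.fixture(scope="session")
def classified(sim):
    """Full three-stage classification of the shared simulation."""
    return classify_proteome(
        sim.proteins, sim.outside_dbs, sim.clade_dbs, sim.knowledgebase
    )


GFF3_3GENE = """##gff-version 3
chr1\ttest\tgene\t101\t400\t.\t+\t.\tID=GA;biotype=protein_coding
chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=GA.1;Parent=GA;representative=1
chr1\ttest\texon\t101\t220\t.\t+\t.\tParent=GA.1
chr1\ttest\texon\t301\t400\t.\t+\t.\tParent=GA.1
chr1\ttest\tCDS\t101\t220\t.\t+\t0\tParent=GA.1
chr1\ttest\tCDS\t301\t400\t.\t+\t0\tParent=GA.1
chr1\ttest\tgene\t601\t900\t.\t-\t.\tID=GB;biotype=protein_coding
chr1\ttest\tmRNA\t601\t900\t.\t-\t.\tID=GB.1;Parent=GB;representative=1;transcript_support=1
chr1\ttest\texon\t601\t900\t.\t-\t.\tParent=GB.1
chr1\ttest\tCDS\t601\t900\t.\t-\t0\tParent=GB.1
chr1\ttest\ttransposable_element_gene\t1001\t1100\t.\t+\t.\tID=GC
chr1\ttest\tmRNA\t1001\t1100\t.\t+\t.\tID=GC.1;Parent=GC
chr1\ttest\texon\t1001\t1100\t.\t+\t.\tParent=GC.1
"""


@pytest.fixture()
def tiny_annotation_files(tmp_path):
    """A hand-written 3-gene GFF3 + FASTA pair on disk."""
    import numpy as np

    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1500)])
    # plant a clean CDS for GB (single exon on the minus strand)
    gff = tmp_path / "tiny.gff3"
    fasta = tmp_path / "tiny.fasta"
    gff.write_text(GFF3_3GENE)
    fasta.write_text(f">chr1\n{seq}\n")
    return gff, fasta
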