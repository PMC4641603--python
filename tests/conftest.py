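import pytest

from unionquant import scenario_presets
from unionquant.annotation import Annotation, Gene, GenomicInterval, Transcript

TOY_GTF = """\
chr1\ttoy\texon\t1001\t3000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.T1";
chr1\ttoy\texon\t4001\t5000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.T1";
chr1\ttoy\texon\t6001\t8000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.T1";
chr1\ttoy\texon\t1001\t3000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.T2";
chr1\ttoy\texon\t6001\t8000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.T2";
chr1\ttoy\texon\t9001\t9600\t.\t+\t.\tgene_id "G2"; transcript_id "G2.T1";
"""


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return str(path)


def make_gene(gene_id, chrom, strand, chains, origin=0):
    """Build a gene from exon chains given as lists of (start, end)."""
    txs = tuple(
        Transcript(
            f"{gene_id}.T{i + 1}",
            gene_id,
            tuple(
                GenomicInterval(chrom, origin + s, origin + e, strand)
                for s, e in chain
            ),
        )
        for i, chain in enumerate(chains)
    )
    return Gene(gene_id, txs)


@pytest.fixture(scope="session")
def fig1_scenario():
    return scenario_presets("fig1", seed=101)


@pytest.fixture(scope="session")
def fig9_scenario():
    return scenario_presets("fig9", seed=202)
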