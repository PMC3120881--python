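import pytest

from asmannot.core import GenomeAssembly, GenomicInterval, Transcript
from asmannot.pipeline import run_pipeline
from asmannot.scenarios import null_scenario


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small event-free dual assembly shared across test modules."""
    return null_scenario(seed=42, n_chrom=2, chrom_length=60_000, n_genes=8, n_snps=20)


@pytest.fixture(scope="session")
def tiny_result(tiny_bundle):
    return run_pipeline(tiny_bundle)


@pytest.fixture
def toy_genome():
    #            1234567890123456789012345678901234567890
    chr1 = "ACGTACGTAAGGTTCCAAGGTTACGTACGTGGCCAATTGG"
    return GenomeAssembly("toy", {"chr1": chr1})


def make_transcript(tid, chrom, exon_coords, strand="+", gene_name=None, evidence=None, cds=None):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    return Transcript(tid, exons, gene_name=gene_name, evidence_accession=evidence, cds=cds)
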