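import numpy as np
import pytest

from ripintegrate.annotation import AlignedRead, Gene, GenomeAnnotation, Transcript


def make_gene(gene_id, exon_lists, strand="+", chrom="chr1", symbol=None):
    """Build a gene from a list of per-transcript exon lists."""
    txs = tuple(
        Transcript(f"{gene_id}.t{i + 1}", tuple(sorted(map(tuple, exons))))
        for i, exons in enumerate(exon_lists)
    )
    return Gene(gene_id, symbol or gene_id.upper(), chrom, strand, txs)


def make_read(read_id, blocks, strand="+", chrom="chr1", unique=True, sample="s1"):
    return AlignedRead(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        blocks=tuple(map(tuple, blocks)),
        unique=unique,
        sample_id=sample,
    )


@pytest.fixture
def toy_annotation():
    """Three disjoint genes; the third is on the minus strand."""
    return GenomeAnnotation(
        [
            make_gene("gA", [[(100, 200), (300, 400), (500, 700)]]),
            make_gene("gB", [[(1000, 1200), (1400, 1600)]]),
            make_gene("gC", [[(2000, 2300)]], strand="-"),
        ]
    )


@pytest.fixture
def overlap_annotation():
    """Two genes whose exons overlap on the same strand (ambiguity tests)."""
    return GenomeAnnotation(
        [
            make_gene("gX", [[(100, 400)]]),
            make_gene("gY", [[(300, 600)]]),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
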