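import pytest

from synfind.genome_model import GeneModel, GenomeAnnotation, assign_ranks
from synfind.homology_io import HomologPair


def make_annotation(genome_id, genes):
    """Build a ranked GenomeAnnotation from (gene_id, chrom, start, end[, strand]) tuples."""
    models = [GeneModel(*g) for g in genes]
    return assign_ranks(GenomeAnnotation(genome_id, models))


def make_pairs(rows):
    """Build a PairSet from (query, target, score[, evalue]) tuples."""
    return {(r[0], r[1]): HomologPair(*r) for r in rows}


def linear_annotation(genome_id, n, chrom="chr1", prefix="g"):
    """n genes in a row on one chromosome, 1 kb apart."""
    return make_annotation(
        genome_id,
        [(f"{prefix}{i}", chrom, i * 1000, i * 1000 + 600) for i in range(n)],
    )


@pytest.fixture
def tiny_query():
    return linear_annotation("q", 10, prefix="q")


@pytest.fixture
def tiny_target():
    return linear_annotation("t", 10, chrom="tchr1", prefix="t")
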