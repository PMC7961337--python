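import numpy as np
import pytest

from intronrank.gene_model import GeneModel
from intronrank.score_table import IntronScoreSet


@pytest.fixture
def three_exon_model():
    """'+' strand transcript with exons (100,200),(300,400),(500,600), fully coding."""
    return GeneModel(
        gene_id="G1",
        transcript_id="T1",
        chrom="chr1",
        strand="+",
        exons=((100, 200), (300, 400), (500, 600)),
        cds_start=100,
        cds_end=600,
        build="hg38",
    )


@pytest.fixture
def three_exon_model_minus(three_exon_model):
    return GeneModel(
        gene_id="G1",
        transcript_id="T1",
        chrom="chr1",
        strand="-",
        exons=three_exon_model.exons,
        cds_start=100,
        cds_end=600,
        build="hg38",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_score_sets(arrays):
    return [
        IntronScoreSet(intron_index=i + 1, scores=np.asarray(a, dtype=float))
        for i, a in enumerate(arrays)
    ]


@pytest.fixture
def abc_score_sets():
    """Three 4-variant introns; intron 1 holds all the top-ranked scores."""
    return make_score_sets(
        [[10, 11, 12, 13], [1, 2, 3, 4], [1.5, 2.5, 3.5, 4.5]]
    )
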