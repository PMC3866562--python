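import numpy as np
import pytest

from corebind.genome import GeneModel, GenomeAnnotation, Interval, IntervalSet, SeqSpace


@pytest.fixture
def space():
    return SeqSpace({"chr1": 100_000, "chr2": 80_000})


@pytest.fixture
def tiny_annotation(space):
    """Two-chromosome annotation with known exon/intron structure."""
    genes = [
        GeneModel("geneA", "chr1", 500, 1500, "+",
                  transcripts=[[(500, 700), (900, 1100), (1300, 1500)]]),
        GeneModel("geneB", "chr1", 2000, 2600, "-",
                  transcripts=[[(2000, 2200), (2400, 2600)]]),
        GeneModel("geneC", "chr2", 16_000, 18_000, "+",
                  transcripts=[[(16_000, 18_000)]]),
    ]
    return GenomeAnnotation(seqspace=space, genes=genes)


def make_set(label, spans, technique="other", fdr_tier=None, space=None):
    return IntervalSet(
        label=label,
        intervals=[Interval(c, s, e) for c, s, e in spans],
        technique=technique,
        fdr_tier=fdr_tier,
        seqspace=space,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
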