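import numpy as np
import pytest

from splicetrap.genomic_model import Genome, GenomicInterval, TranscriptModel


def make_model(exons, strand="+", chrom="chr1", tid="tx", gid=None):
    return TranscriptModel(
        tid,
        gid or tid,
        chrom,
        strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_genome():
    # one 60-nt chromosome with a canonical GT..AG intron at 20-40
    seq = "ACGTACGTACGTACGTACGT" + "GT" + "A" * 16 + "AG" + "TTGGCCAATTGGCCAATTGG"
    return Genome({"chr1": seq})
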