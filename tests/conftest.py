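import numpy as np
import pytest

from erviso import simulate as sim


@pytest.fixture
def locus_spec():
    """Default toy locus: long/short/canonical forms plus repeat parts."""
    return sim.LocusSpec()


@pytest.fixture
def toy_regions(locus_spec):
    return sim.locus_regions(locus_spec)


@pytest.fixture
def toy_transcripts(locus_spec):
    return sim.locus_transcripts(locus_spec)


def random_transcript(rng: np.random.Generator, chrom="chrA", max_pos=10_000, tid="t"):
    """A random transcript with 1-4 disjoint exons."""
    from erviso.annotation import TranscriptModel

    n_exons = int(rng.integers(1, 5))
    cuts = np.sort(rng.choice(max_pos, size=2 * n_exons, replace=False))
    exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_exons)]
    strand = rng.choice(["+", "-"])
    return TranscriptModel(tid, "g", chrom, str(strand), exons)
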