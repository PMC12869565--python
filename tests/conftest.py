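import numpy as np
import pytest

from wrapstate.fragments import FragmentSet
from wrapstate.genome import GeneRecord, Genome, GenomicInterval


@pytest.fixture
def genome():
    return Genome({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def genes(genome):
    return [
        GeneRecord("g1", "chr1", 5_000, "+"),
        GeneRecord("g2", "chr1", 20_000, "-"),
        GeneRecord("g3", "chr2", 10_000, "+"),
    ]


def random_intervals(rng, genome, n, max_len=500):
    """Helper shared by oracle tests: n random valid intervals."""
    names = genome.names
    lens = np.asarray([genome[c] for c in names], dtype=np.int64)
    ci = rng.integers(0, len(names), size=n)
    lengths = rng.integers(1, max_len + 1, size=n)
    starts = rng.integers(0, lens[ci] - lengths + 1)
    return [
        GenomicInterval(names[c], int(s), int(s + l), name=f"iv{i}")
        for i, (c, s, l) in enumerate(zip(ci, starts, lengths))
    ]


def random_fragset(rng, genome, n, max_len=400, condition="c", replicate="r"):
    names = genome.names
    lens = np.asarray([genome[c] for c in names], dtype=np.int64)
    ci = rng.integers(0, len(names), size=n)
    lengths = rng.integers(30, max_len + 1, size=n)
    starts = rng.integers(0, lens[ci] - lengths + 1)
    return FragmentSet(
        condition,
        replicate,
        np.asarray(names, dtype=object)[ci],
        starts.astype(np.int64),
        (starts + lengths).astype(np.int64),
    )
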