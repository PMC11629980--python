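import numpy as np
import pytest

from epistates.genome_core import (
    GeneRecord,
    GenomeModel,
    GenomicInterval,
    StateSegmentation,
)


@pytest.fixture
def genome():
    return GenomeModel({"chr1": 100_000, "chr2": 80_000})


@pytest.fixture
def plus_gene():
    return GeneRecord("gA", "chr1", 5_000, 9_000, "+", {"brain": 5.0, "liver": 0.5})


@pytest.fixture
def minus_gene():
    return GeneRecord("gB", "chr2", 20_000, 26_000, "-", {"brain": 0.0, "liver": 12.0})


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos - 1))
        end = start + int(rng.integers(1, 200))
        out.append(GenomicInterval(chrom, start, end))
    return out


def brute_force_overlaps(query, subject):
    """O(n*m) oracle for the interval join."""
    pairs = []
    for qi, q in enumerate(query):
        for si, s in enumerate(subject):
            if q.chrom != s.chrom:
                continue
            bp = min(q.end, s.end) - max(q.start, s.start)
            if bp > 0:
                pairs.append((qi, si, bp))
    return pairs


def make_track(segments, tissue="brain"):
    return StateSegmentation(
        tissue=tissue,
        segments=sorted(segments, key=GenomicInterval.sort_key),
    )
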