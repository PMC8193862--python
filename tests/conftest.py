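from __future__ import annotations

import random

import pytest

from umidedup.fastq_io import ReadRecord


def make_read(seq: str, quals=None, read_id: str = "r") -> ReadRecord:
    if quals is None:
        quals = [30] * len(seq)
    elif isinstance(quals, int):
        quals = [quals] * len(seq)
    return ReadRecord(read_id, seq, tuple(quals))


def random_group(rng: random.Random, max_reads: int = 10, max_len: int = 20):
    """A random pile of equal-length reads over ACGTN with random qualities."""
    n = rng.randint(1, max_reads)
    length = rng.randint(1, max_len)
    return [
        make_read(
            "".join(rng.choice("ACGTN") for _ in range(length)),
            [rng.randint(0, 41) for _ in range(length)],
            read_id=f"r{i}",
        )
        for i in range(n)
    ]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
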