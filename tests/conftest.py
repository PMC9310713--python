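"""Shared fixtures and independent oracles.

The naive mapper here is the brute-force oracle for exact mapping: it
compares every read against every window of every reference on both strands
with plain string equality, independently of the package's search path.
"""

from __future__ import annotations

import numpy as np
import pytest

from artsrna import Hit, ReadSet, ReferenceSeq
from artsrna._seq import revcomp

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def random_library(
    rng: np.random.Generator,
    ref: ReferenceSeq,
    n_reads: int = 30,
    p_from_ref: float = 0.7,
) -> ReadSet:
    """Random library mixing reference substrings (both strands) and random
    sequences, with random multiplicities."""
    reads = []
    for _ in range(n_reads):
        length = int(rng.integers(19, 25))
        if rng.random() < p_from_ref and len(ref.sequence) >= length:
            start = int(rng.integers(0, len(ref.sequence) - length + 1))
            seq = ref.sequence[start : start + length]
            if rng.random() < 0.5:
                seq = revcomp(seq)
        else:
            seq = random_seq(rng, length)
        reads.append((seq, int(rng.integers(1, 6))))
    return ReadSet(reads=tuple(reads), library_id="rand")


def naive_map(reads: ReadSet, refs: list[ReferenceSeq]) -> list[Hit]:
    """All-window substring scan: the O(n*m) oracle for map_exact."""
    hits: list[Hit] = []
    for seq, count in reads.reads:
        L = len(seq)
        rc = revcomp(seq)
        for ref in refs:
            found = []
            for start in range(len(ref.sequence) - L + 1):
                window = ref.sequence[start : start + L]
                if window == seq:
                    found.append(("+", start))
                if window == rc:
                    found.append(("-", start))
            if not found:
                continue
            w = 1.0 / len(found)
            hits.extend(
                Hit(seq, count, ref.ref_id, strand, s, s + L, w) for strand, s in found
            )
    hits.sort(key=lambda h: (h.ref_id, h.start, h.strand, h.read_seq))
    return hits


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
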