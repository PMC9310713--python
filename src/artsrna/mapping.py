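"""Exact both-strand read mapping and per-position count/RPM profiles.

Every unique read is searched against the forward sequence of each reference
(+ strand) and, via its reverse complement, against the reverse strand
(- strand); no mismatches or gaps are allowed.  (-)-strand hits are reported
in forward coordinates of the matched interval so that profiles, processing
offsets and phasing registers all share one coordinate system.  A read
hitting k positions within one reference carries weight 1/k at each, so
weighted counts conserve read counts per reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal, Sequence

import pandas as pd

from ._seq import find_occurrences, revcomp
from .io import ReadSet
from .reference import ReferenceSeq

DenominatorMode = Literal["library_total", "mapped_total"]


@dataclass(frozen=True)
class Hit:
    read_seq: str
    count: int
    ref_id: str
    strand: Literal["+", "-"]
    start: int
    end: int
    weight: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def weighted_count(self) -> float:
        return self.count * self.weight


def map_exact(reads: ReadSet, refs: Sequence[ReferenceSeq]) -> list[Hit]:
    """Map every read exactly to both strands of every reference.

    Returns one Hit per occurrence; reads with no match anywhere are simply
    absent.  Output order is (ref_id, start, strand, read_seq) for
    deterministic downstream tables.
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    hits: list[Hit] = []
    for seq, count in reads.reads:
        rc = revcomp(seq)
        for ref in refs:
            plus = find_occurrences(ref.sequence, seq)
            minus = find_occurrences(ref.sequence, rc)
            k = len(plus) + len(minus)
            if k == 0:
                continue
            w = 1.0 / k
            L = len(seq)
            hits.extend(Hit(seq, count, ref.ref_id, "+", s, s + L, w) for s in plus)
            hits.extend(Hit(seq, count, ref.ref_id, "-", s, s + L, w) for s in minus)
    hits.sort(key=lambda h: (h.ref_id, h.start, h.strand, h.read_seq))
    return hits


@dataclass
class PositionProfile:
    """Weighted counts and RPM per (strand, start, read length) of one reference."""

    ref_id: str
    table: pd.DataFrame  # columns: strand, start0, length, count, rpm
    library_total: int
    denominator: int
    denominator_mode: DenominatorMode


def mapped_total(hits: Iterable[Hit], library: ReadSet) -> int:
    """Total read count (by multiplicity) of library sequences with >= 1 hit."""
    mapped = {h.read_seq for h in hits}
    return sum(count for seq, count in library.reads if seq in mapped)


def build_profile(
    hits: Sequence[Hit],
    library: ReadSet,
    denominator: DenominatorMode = "library_total",
) -> dict[str, PositionProfile]:
    """Aggregate hits into one per-position profile per reference.

    RPM = 1e6 * weighted_count / denominator, where the denominator is the
    library's total clean reads (default) or the total reads with at least
    one hit ("RPM mapped reads").
    """
    if denominator == "library_total":
        denom = library.total_reads
    elif denominator == "mapped_total":
        denom = mapped_total(hits, library)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if denom == 0:
        raise ValueError("empty library: RPM denominator is zero")

    rows = [
        (h.ref_id, h.strand, h.start, h.length, h.weighted_count) for h in hits
    ]
    frame = pd.DataFrame(rows, columns=["ref_id", "strand", "start0", "length", "count"])
    profiles: dict[str, PositionProfile] = {}
    for ref_id, sub in frame.groupby("ref_id", sort=True):
        table = (
            sub.groupby(["strand", "start0", "length"], as_index=False)["count"]
            .sum()
            .sort_values(["strand", "start0", "length"], ignore_index=True)
        )
        table["rpm"] = 1e6 * table["count"] / denom
        profiles[str(ref_id)] = PositionProfile(
            ref_id=str(ref_id),
            table=table,
            library_total=library.total_reads,
            denominator=denom,
            denominator_mode=denominator,
        )
    return profiles


def sequence_rpm(hits: Sequence[Hit], sequence: str, profile: PositionProfile) -> float:
    """RPM of reads whose sequence is exactly ``sequence`` on the profile's
    reference (weights of one read sum to 1 per reference, so this equals
    count/denominator regardless of multi-mapping)."""
    total = sum(
        h.weighted_count
        for h in hits
        if h.ref_id == profile.ref_id and h.read_seq == sequence
    )
    return 1e6 * total / profile.denominator


def strand_accumulation(
    hits: Sequence[Hit], guide: str, star: str, profile: PositionProfile
) -> tuple[float, float]:
    """RPM of the exact guide and star strand sequences (the duplex
    accumulation bar values).  Reads matching neither contribute to neither."""
    if guide == star:
        raise ValueError("guide and star sequences must differ")
    return sequence_rpm(hits, guide, profile), sequence_rpm(hits, star, profile)
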