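"""Precursor and target geometry.

Coordinates are 0-based, half-open, on the (+) strand of each reference.
A precursor is either a miRNA-style foldback (the guide is excised by DCL1
at an annotated position) or a TAS-style transcript (the guide occupies a
21-nt phased slot downstream of a trigger-miRNA cleavage site and is
released by DCL4).  The target transcript carries the art-sRNA target site;
AGO-guided cleavage falls between the target nucleotides paired to sRNA
positions 10 and 11 (counting from the sRNA 5' end), so the first nucleotide
of the 3' cleavage fragment is ``p0 = start + L - 10``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from ._seq import complement, hamming, revcomp
from .errors import ConfigError


@dataclass(frozen=True)
class ReferenceSeq:
    ref_id: str
    sequence: str
    role: Literal["precursor", "transcript"] = "transcript"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.ref_id}: empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"reference {self.ref_id}: non-ACGT letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrecursorSpec:
    """A precursor reference plus the expected mature-sRNA coordinates."""

    ref: ReferenceSeq
    kind: Literal["mir_foldback", "tas_transcript"]
    guide_start: int
    guide_length: int
    star_start: int | None = None
    trigger_cleavage_pos: int | None = None  # tas_transcript only
    phase_cycle: int = 21

    def __post_init__(self) -> None:
        n = len(self.ref)
        if not 19 <= self.guide_length <= 24:
            raise ConfigError(f"guide_length {self.guide_length} outside [19, 24]")
        if not 0 <= self.guide_start or self.guide_start + self.guide_length > n:
            raise ConfigError("guide interval exceeds precursor bounds")
        if self.kind == "tas_transcript":
            if self.trigger_cleavage_pos is None:
                raise ConfigError("tas_transcript requires trigger_cleavage_pos")
            delta = self.guide_start - self.trigger_cleavage_pos
            if delta <= 0 or delta % self.phase_cycle != 0:
                raise ConfigError(
                    "guide must sit a whole number of phase cycles downstream "
                    "of the trigger cleavage position"
                )
        if self.star_start is not None:
            s0, s1 = self.star_start, self.star_start + self.guide_length
            if s0 < 0 or s1 > n:
                raise ConfigError("star interval exceeds precursor bounds")
            if s0 < self.guide_start + self.guide_length and self.guide_start < s1:
                raise ConfigError("star interval overlaps guide interval")

    @property
    def guide_sequence(self) -> str:
        return self.ref.sequence[self.guide_start : self.guide_start + self.guide_length]

    @property
    def expected_five_prime(self) -> int:
        """Anchor for processing-accuracy offsets: the expected mature 5' end
        (the guide start; for TAS precursors this is the guide's phased slot,
        e.g. 3'D2[+])."""
        return self.guide_start

    def star_sequence(self) -> str:
        """Annotated star strand if present; otherwise the duplex partner
        derived in precursor context (its 2-nt 3' overhang padded from the
        precursor bases flanking the guide), falling back to the idealized
        complement-padded derivation at the precursor edge."""
        if self.star_start is not None:
            return self.ref.sequence[self.star_start : self.star_start + self.guide_length]
        gs, L = self.guide_start, self.guide_length
        if gs + L + 2 <= len(self.ref):
            # revcomp(star)[i] == guide[i+2], overhang bases from the precursor
            return revcomp(self.ref.sequence[gs + 2 : gs + L + 2])
        return derive_star(self.guide_sequence)


@dataclass(frozen=True)
class TargetSite:
    transcript_id: str
    start: int
    end: int
    mismatches: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CleavageSite:
    """p0 = 0-based index of the first nucleotide of the 3' cleavage fragment."""

    transcript_id: str
    p0: int

    def __post_init__(self) -> None:
        if self.p0 < 0:
            raise ValueError("p0 must be non-negative")


def find_target_site(
    srna: str, transcript: ReferenceSeq, max_mismatches: int = 0
) -> list[TargetSite]:
    """All transcript windows pairing the sRNA with <= max_mismatches.

    An sRNA pairs the (+) transcript in antiparallel orientation, so a window
    is compared against the reverse complement of the sRNA (Hamming distance,
    no gaps, no G:U wobble awareness).  Sorted by (mismatches, start).
    """
    if not 19 <= len(srna) <= 24:
        raise ValueError(f"sRNA length {len(srna)} outside [19, 24]")
    pattern = revcomp(srna)
    L = len(pattern)
    seq = transcript.sequence
    sites = [
        TargetSite(transcript.ref_id, s, s + L, mismatches=d)
        for s in range(len(seq) - L + 1)
        if (d := hamming(seq[s : s + L], pattern)) <= max_mismatches
    ]
    sites.sort(key=lambda t: (t.mismatches, t.start))
    return sites


def predict_cleavage(site: TargetSite) -> CleavageSite:
    """Cleavage between target nucleotides paired to sRNA positions 10 and 11.

    sRNA position k (1-based from its 5' end) pairs target index
    ``start + L - k``, so the 3' fragment begins at ``p0 = start + L - 10``.
    """
    L = site.length
    if L < 11:
        raise ValueError(f"no canonical cleavage geometry for sRNA length {L} < 11")
    return CleavageSite(site.transcript_id, site.start + L - 10)


def phase_positions(
    cleavage: CleavageSite,
    cycle: int = 21,
    n_cycles: int = 1,
    *,
    ref_length: int | None = None,
) -> list[int]:
    """Expected 5' ends of phased (+)-strand siRNAs: p0, p0+cycle, ...

    These are the D1[+], D2[+], ... register-1 starts downstream of the
    cleavage site.  When ``ref_length`` is given, starts that cannot hold a
    full cycle-length sRNA on the transcript are truncated from the list.
    """
    if cycle < 1 or n_cycles < 1:
        raise ValueError("cycle and n_cycles must be >= 1")
    positions = [cleavage.p0 + i * cycle for i in range(n_cycles)]
    if ref_length is not None:
        positions = [p for p in positions if p + cycle <= ref_length]
    return positions


def derive_star(guide: str, overhang: int = 2) -> str:
    """Star (passenger) strand of a perfectly complementary duplex with
    ``overhang``-nt 3' overhangs on both strands.

    Defining identity: ``revcomp(star)[i] == guide[i + overhang]`` for all
    valid i; the bases this leaves free are filled with the complement of
    ``guide[0:overhang]``.  Real foldbacks contain mismatches, so an
    annotated star sequence (PrecursorSpec.star_start) takes precedence over
    this idealized derivation.
    """
    L = len(guide)
    if L < 4 or L < overhang + 2:
        raise ValueError(f"guide too short ({L} nt) to form a duplex")
    star = [""] * L
    for i in range(L - overhang):
        # revcomp(star)[i] = complement(star[L-1-i]) must equal guide[i+overhang]
        star[L - 1 - i] = complement(guide[i + overhang])
    for j in range(overhang):
        star[j] = complement(guide[j])
    return "".join(star)
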