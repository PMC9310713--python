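"""Phasing-register analysis of target-derived secondary siRNAs.

After an sRNA/AGO complex cleaves its target, RDR6 can convert one cleavage
fragment to dsRNA which DCL4 dices into 21-nt siRNA duplexes *in phase* with
the cleavage site.  Reads from such transitivity therefore pile up in one of
21 residue classes ("registers") of start position modulo 21, anchored at
p0, the first nucleotide of the 3' cleavage fragment: register 1 holds reads
whose 5' end is congruent to p0, i.e. begins immediately after the cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .mapping import Hit
from .reference import CleavageSite

StrandMode = Literal["plus_only", "both"]


@dataclass
class PhasingTable:
    """Weighted counts and proportions per register (1..cycle)."""

    counts: np.ndarray        # shape (cycle,), weighted counts, index 0 = register 1
    n_reads: float            # total qualifying weighted count
    p0: int
    cycle: int

    @property
    def proportions(self) -> np.ndarray:
        if self.n_reads == 0:
            return np.zeros(self.cycle)
        return self.counts / self.n_reads

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "register": np.arange(1, self.cycle + 1),
                "weighted_count": self.counts,
                "proportion": self.proportions,
            }
        )


def phasing_table(
    hits: Sequence[Hit],
    cleavage: CleavageSite,
    cycle: int = 21,
    strand_mode: StrandMode = "plus_only",
) -> PhasingTable:
    """Register table of cycle-length reads downstream of the cleavage site.

    Qualifying reads are exactly ``cycle`` nt long (21 by default), lie on
    the target transcript, and start at or downstream of p0 (reads upstream
    of or straddling the cut are excluded).  Register = ((start - p0) mod
    cycle) + 1.  In ``both`` mode, (-)-strand reads are included with the
    canonical 2-nt duplex-overhang correction, ((start + 2 - p0) mod cycle)
    + 1, and may begin up to 2 nt before p0 (the duplex partner of an
    in-phase (+) siRNA does).
    """
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    counts = np.zeros(cycle)
    for h in hits:
        if h.ref_id != cleavage.transcript_id or h.length != cycle:
            continue
        if h.strand == "+":
            if h.start < cleavage.p0:
                continue
            register = (h.start - cleavage.p0) % cycle
        elif strand_mode == "both":
            if h.start + 2 < cleavage.p0:
                continue
            register = (h.start + 2 - cleavage.p0) % cycle
        else:
            continue
        counts[register] += h.weighted_count
    return PhasingTable(counts=counts, n_reads=float(counts.sum()), p0=cleavage.p0, cycle=cycle)


def phased_fraction(table: PhasingTable, register: int = 1) -> float:
    """Proportion of qualifying reads in the requested register (1-based)."""
    if not 1 <= register <= table.cycle:
        raise ValueError(f"register must be in [1, {table.cycle}]")
    if table.n_reads == 0:
        raise UndefinedStatisticError("no qualifying phased-analysis reads")
    return float(table.proportions[register - 1])
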