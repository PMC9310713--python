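"""Precursor processing-fidelity statistics.

DCL enzymes excise the mature art-sRNA from its precursor at a defined
position; imprecise processing shows up in sequencing as reads whose 5' end
is offset from the expected mature 5' end and/or whose length deviates from
the expected mature length.  This module tabulates (+)-strand precursor reads
by (5'-offset, length) and derives two summary statistics from the table:

* the *exact mature fraction* (offset 0 and the exact mature length) — the
  pie-chart "accurately processed" share;
* the *windowed accuracy* — the fraction of 19-24-nt (+) reads whose 5' end
  maps within +/-4 nt of the expected mature 5' end, any length.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import UndefinedStatisticError
from .mapping import Hit
from .reference import PrecursorSpec


@dataclass
class FormClassification:
    """Weighted (+)-strand read counts keyed by (5'-offset, read length).

    ``offset`` = hit start - expected mature 5' position; ``denominator`` is
    the total weighted count of all (+)-strand precursor reads in the length
    range (every such read occupies exactly one cell).
    """

    cells: dict[tuple[int, int], float]
    denominator: float
    anchor: int
    length_range: tuple[int, int]
    guide_length: int

    def fraction(self, offset: int, length: int) -> float:
        if self.denominator == 0:
            raise UndefinedStatisticError("no qualifying (+) precursor reads")
        return self.cells.get((offset, length), 0.0) / self.denominator

    def to_frame(self) -> pd.DataFrame:
        """Tidy table over at least offsets [-4, 4] x the length range."""
        lo, hi = self.length_range
        keys = {(o, L) for o in range(-4, 5) for L in range(lo, hi + 1)}
        keys.update(self.cells)
        rows = []
        for offset, length in sorted(keys):
            wc = self.cells.get((offset, length), 0.0)
            frac = wc / self.denominator if self.denominator > 0 else float("nan")
            rows.append((offset, length, wc, frac))
        return pd.DataFrame(rows, columns=["offset", "length", "weighted_count", "fraction"])


def classify_forms(
    hits: Sequence[Hit],
    spec: PrecursorSpec,
    length_range: tuple[int, int] = (19, 24),
) -> FormClassification:
    """Tabulate (+)-strand precursor reads by 5'-offset and length.

    The offset anchor is the expected mature 5' end: the guide start for a
    foldback, the guide's phased slot (e.g. 3'D2[+]) for a TAS transcript.
    (-)-strand reads never enter any cell or the denominator.
    """
    lo, hi = length_range
    anchor = spec.expected_five_prime
    cells: dict[tuple[int, int], float] = defaultdict(float)
    denominator = 0.0
    for h in hits:
        if h.ref_id != spec.ref.ref_id or h.strand != "+":
            continue
        if not lo <= h.length <= hi:
            continue
        denominator += h.weighted_count
        cells[(h.start - anchor, h.length)] += h.weighted_count
    return FormClassification(
        cells=dict(cells),
        denominator=denominator,
        anchor=anchor,
        length_range=length_range,
        guide_length=spec.guide_length,
    )


def processing_accuracy(
    cls: FormClassification,
    window: float = 4,
    exact_length: int | None = None,
) -> float:
    """Fraction of qualifying reads with |5'-offset| <= window (and, when
    ``exact_length`` is given, exactly that read length).

    ``window=0, exact_length=guide_length`` gives the exact mature fraction;
    ``window=4, exact_length=None`` gives the +/-4-nt windowed accuracy.
    """
    if cls.denominator == 0:
        raise UndefinedStatisticError(
            "processing accuracy undefined: no 19-24-nt (+) reads on the precursor"
        )
    total = sum(
        wc
        for (offset, length), wc in cls.cells.items()
        if abs(offset) <= window and (exact_length is None or length == exact_length)
    )
    return total / cls.denominator


def exact_mature_fraction(cls: FormClassification) -> float:
    """Pie-chart share: reads that are precisely the expected mature sRNA
    (offset 0, exact mature length — on the precursor this cell *is* the
    guide sequence)."""
    return processing_accuracy(cls, window=0, exact_length=cls.guide_length)


def summary_frame(cls: FormClassification) -> pd.DataFrame:
    """Both accuracy framings as a small tidy table (NA-free only when the
    denominator is positive; callers handle UndefinedStatisticError)."""
    rows = [
        ("exact_mature_fraction", 0, cls.guide_length, exact_mature_fraction(cls)),
        ("windowed_accuracy", 4, "any", processing_accuracy(cls, window=4)),
    ]
    return pd.DataFrame(rows, columns=["metric", "window", "length_filter", "value"])
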