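"""Tiny DNA-string helpers used throughout the package.

All sequences are uppercase DNA over {A,C,G,T,N}; RNA input (U) is converted
to DNA at parse time. N is carried through parsing but, because the mapper is
exact, an N never produces a hit.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_ALPHABET = frozenset("ACGTN")


def normalize(seq: str) -> str:
    """Uppercase and convert U→T."""
    return seq.upper().replace("U", "T")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_occurrences(text: str, pattern: str) -> list[int]:
    """All (possibly overlapping) start indices of ``pattern`` in ``text``."""
    if not pattern:
        raise ValueError("empty pattern")
    out: list[int] = []
    i = text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
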