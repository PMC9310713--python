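"""Reading and writing of read libraries and report tables.

Libraries arrive either as raw FASTQ/FASTA (one record per sequenced read,
already adapter-trimmed) or as collapsed FASTA, the fastx_collapser-style
dialect in which each record is a unique sequence whose read count is encoded
in the header (``>seq1-532``).  Quality strings are ignored throughout: the
pipeline operates on clean reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd
from Bio import SeqIO

from ._seq import VALID_ALPHABET, normalize
from .errors import ParseError

ReadFormat = Literal["fastq", "fasta", "collapsed_fasta"]

_COLLAPSED_HEADER = {
    "-": re.compile(r"^(?P<name>.*)-(?P<count>\d+)$"),
    "_": re.compile(r"^(?P<name>.*)_(?P<count>\d+)$"),
}


@dataclass(frozen=True)
class ReadSet:
    """A small-RNA library: (sequence, count) pairs plus provenance.

    ``reads`` may hold duplicate sequences (e.g. straight from FASTQ, count 1
    each) until :func:`collapse` merges them.  Counts are strictly positive;
    ``total_reads`` is always the sum of counts.
    """

    reads: tuple[tuple[str, int], ...]
    library_id: str = ""

    def __post_init__(self) -> None:
        for seq, count in self.reads:
            if count <= 0 or count != int(count):
                raise ValueError(f"read count must be a positive integer, got {count!r}")
            bad = set(seq) - VALID_ALPHABET
            if bad or not seq:
                raise ValueError(f"invalid sequence {seq!r} (letters {sorted(bad)})")

    @property
    def total_reads(self) -> int:
        return sum(count for _, count in self.reads)

    @property
    def n_unique(self) -> int:
        return len({seq for seq, _ in self.reads})

    def __len__(self) -> int:
        return len(self.reads)


def _validated(seq: str, where: str) -> str:
    seq = normalize(seq)
    if not seq or set(seq) - VALID_ALPHABET:
        raise ParseError(f"{where}: sequence {seq!r} contains non-DNA letters")
    return seq


def _fasta_header_lines(path: Path) -> list[int]:
    """1-based line numbers of FASTA headers, for error reporting."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                out.append(lineno)
    return out


def parse_reads(
    path: str | Path,
    format: ReadFormat,
    *,
    library_id: str | None = None,
    collapsed_sep: str = "-",
) -> ReadSet:
    """Parse a read library into a :class:`ReadSet`.

    For ``fastq``/``fasta`` every record contributes count 1 (collapse
    afterwards); for ``collapsed_fasta`` the count is taken from the header,
    split on ``collapsed_sep`` (``-`` by default, ``_`` accepted).
    Sequences are uppercased and U is converted to T.  An empty file yields
    an empty ReadSet.
    """
    path = Path(path)
    lib = library_id if library_id is not None else path.stem
    if format not in ("fastq", "fasta", "collapsed_fasta"):
        raise ValueError(f"unknown read format {format!r}")
    if path.stat().st_size == 0:
        return ReadSet(reads=(), library_id=lib)

    reads: list[tuple[str, int]] = []
    if format == "fastq":
        try:
            for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
                where = f"{path.name} line {4 * i + 1}"
                reads.append((_validated(str(rec.seq), where), 1))
        except ValueError as exc:  # malformed 4-line structure
            raise ParseError(f"{path.name} near line {4 * len(reads) + 1}: {exc}") from exc
        return ReadSet(reads=tuple(reads), library_id=lib)

    header_lines = _fasta_header_lines(path)
    if not header_lines:
        raise ParseError(f"{path.name} line 1: no FASTA headers found")
    pattern = _COLLAPSED_HEADER.get(collapsed_sep)
    if format == "collapsed_fasta" and pattern is None:
        raise ValueError(f"collapsed_sep must be '-' or '_', got {collapsed_sep!r}")
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        where = f"{path.name} line {header_lines[i]}"
        seq = _validated(str(rec.seq), where)
        if format == "fasta":
            reads.append((seq, 1))
        else:
            m = pattern.match(rec.id)
            if m is None or int(m.group("count")) <= 0:
                raise ParseError(
                    f"{where}: collapsed header {rec.id!r} does not end in "
                    f"'{collapsed_sep}<positive count>'"
                )
            reads.append((seq, int(m.group("count"))))
    return ReadSet(reads=tuple(reads), library_id=lib)


def collapse(reads: ReadSet) -> ReadSet:
    """Merge identical sequences, summing counts.

    Total read count is conserved; output order is lexicographic by sequence
    so that repeated runs are byte-identical.
    """
    tally: dict[str, int] = {}
    for seq, count in reads.reads:
        tally[seq] = tally.get(seq, 0) + count
    merged = tuple(sorted(tally.items()))
    return ReadSet(reads=merged, library_id=reads.library_id)


def write_fasta(reads: ReadSet, path: str | Path, *, collapsed: bool = False) -> Path:
    """Write a ReadSet as FASTA; with ``collapsed=True`` use the
    ``>seq{rank}-{count}`` header dialect (input order is preserved)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rank, (seq, count) in enumerate(reads.reads, start=1):
            if collapsed:
                fh.write(f">seq{rank}-{count}\n{seq}\n")
            else:
                for _ in range(count):
                    fh.write(f">seq{rank}\n{seq}\n")
    return path


@dataclass
class ReportBundle:
    """Container for every table one analysis run can produce.

    Any field may be None (statistic not computed for this library); the
    run summary is a flat mapping written as ``key<TAB>value`` lines.
    """

    processing: pd.DataFrame | None = None          # offset, length, weighted_count, fraction
    processing_summary: pd.DataFrame | None = None  # metric, window, length_filter, value
    phasing: pd.DataFrame | None = None             # register, weighted_count, proportion
    strand_rpm: pd.DataFrame | None = None          # role, sequence, rpm
    profile: pd.DataFrame | None = None             # ref_id, strand, start0, length, count, rpm
    hits: pd.DataFrame | None = None                # ref_id, strand, start0, end0, ...
    summary: dict[str, object] = field(default_factory=dict)


_TABLE_FIELDS = ("processing", "processing_summary", "phasing", "strand_rpm", "profile", "hits")


def write_report(bundle: ReportBundle, out_dir: str | Path, *, prefix: str = "") -> list[Path]:
    """Write every present table as TSV plus the run summary; return the manifest.

    Output is deterministic: no timestamps, stable float formatting, sorted
    summary keys.  Re-running on identical input is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"{prefix}." if prefix else ""
    manifest: list[Path] = []
    for name in _TABLE_FIELDS:
        table = getattr(bundle, name)
        if table is None:
            continue
        dest = out_dir / f"{tag}{name}.tsv"
        table.to_csv(dest, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        manifest.append(dest)
    dest = out_dir / f"{tag}run_summary.txt"
    with open(dest, "w") as fh:
        for key in sorted(bundle.summary):
            fh.write(f"{key}\t{bundle.summary[key]}\n")
    manifest.append(dest)
    return manifest


def read_table(path: str | Path) -> pd.DataFrame:
    """Re-read a TSV report table (round-trip counterpart of write_report)."""
    return pd.read_csv(path, sep="\t")


def read_summary(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                key, _, value = line.rstrip("\n").partition("\t")
                out[key] = value
    return out
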