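"""Generative simulator of artificial-sRNA sequencing libraries.

A simulated library is a mixture over read classes that mirrors art-sRNA
biogenesis:

* ``guide_accurate`` — perfectly processed mature guide reads (DCL excision
  at the annotated position and length);
* ``guide_jitter``  — imprecisely processed variants: precursor substrings at
  a 5'-offset/length drawn from a jitter table;
* ``star``          — the passenger strand of the duplex;
* ``degradation``   — uniform random (+)-strand precursor fragments
  (19-24 nt), the unstructured decay background on the precursor;
* ``phased_in`` / ``phased_off`` — transitivity products: 21-nt target
  substrings downstream of the sRNA-guided cleavage site, starting on a
  21-nt phase position with probability ``phase_fidelity``, else uniformly
  on an off-phase downstream position;
* ``background``    — random sequences rejection-sampled to occur in no
  reference on either strand, so "unmapped" is a verifiable truth label.

Every read carries a truth label, and :func:`truth_expectations` computes
the exact expectation of each pipeline statistic by enumerating the finite
support of each class with its probability — no sampling involved — which
recovery tests use as the oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from ._seq import revcomp
from .errors import ConfigError
from .io import ReadSet
from .mapping import map_exact
from .reference import (
    CleavageSite,
    PrecursorSpec,
    ReferenceSeq,
    TargetSite,
    derive_star,
    phase_positions,
    predict_cleavage,
)

CLASSES = (
    "guide_accurate",
    "guide_jitter",
    "star",
    "degradation",
    "phased_in",
    "phased_off",
    "background",
)

_LEN_RANGE = (19, 24)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated library.

    Mixture weights must sum to 1; the jitter table is a probability table
    over (5'-offset, length) cells excluding the accurate cell
    (0, guide_length).  ``phase_fidelity`` is the probability that a phased
    read starts exactly on a 21-nt phase position downstream of the cleavage
    site.
    """

    seed: int
    n_reads: int
    precursor: PrecursorSpec
    target: ReferenceSeq
    target_site: TargetSite
    w_guide_accurate: float
    w_guide_jitter: float
    w_star: float
    w_degradation: float
    w_phased: float
    w_background: float
    jitter: tuple[tuple[tuple[int, int], float], ...] = ()
    phase_fidelity: float = 0.394
    n_cycles: int = 8
    minus_strand_phased: bool = False
    require_5prime_u: bool = False

    # -- derived geometry ---------------------------------------------------

    @property
    def weights(self) -> dict[str, float]:
        return {
            "guide_accurate": self.w_guide_accurate,
            "guide_jitter": self.w_guide_jitter,
            "star": self.w_star,
            "degradation": self.w_degradation,
            "phased": self.w_phased,
            "background": self.w_background,
        }

    @property
    def guide(self) -> str:
        return self.precursor.guide_sequence

    @property
    def star_seq(self) -> str:
        return self.precursor.star_sequence()

    @property
    def cleavage(self) -> CleavageSite:
        return predict_cleavage(self.target_site)

    def phase_position_list(self) -> list[int]:
        return phase_positions(
            self.cleavage, cycle=21, n_cycles=self.n_cycles, ref_length=len(self.target)
        )

    def off_phase_starts(self) -> list[int]:
        p0 = self.cleavage.p0
        return [
            s
            for s in range(p0, len(self.target) - 21 + 1)
            if (s - p0) % 21 != 0
        ]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        w = self.weights
        if any(v < 0 for v in w.values()):
            raise ConfigError("mixture weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ConfigError(f"mixture weights sum to {sum(w.values())!r}, not 1")
        if self.n_reads <= 0:
            raise ConfigError("n_reads must be positive")
        if not 0.0 <= self.phase_fidelity <= 1.0:
            raise ConfigError("phase_fidelity must be in [0, 1]")
        if self.require_5prime_u and not self.guide.startswith("T"):
            raise ConfigError("guide must begin with U (T) when 5'U is required")
        if self.w_guide_jitter > 0:
            if not self.jitter:
                raise ConfigError("guide_jitter weight > 0 requires a jitter table")
            total = sum(p for _, p in self.jitter)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"jitter table sums to {total!r}, not 1")
            gs, gl, n = self.precursor.guide_start, self.precursor.guide_length, len(
                self.precursor.ref
            )
            for (offset, length), p in self.jitter:
                if p < 0:
                    raise ConfigError("jitter probabilities must be non-negative")
                if (offset, length) == (0, gl):
                    raise ConfigError("jitter table must exclude the accurate cell")
                if gs + offset < 0 or gs + offset + length > n:
                    raise ConfigError(
                        f"jitter cell (offset={offset}, length={length}) exceeds "
                        "precursor bounds"
                    )
        if self.w_phased > 0:
            if self.phase_fidelity > 0 and not self.phase_position_list():
                raise ConfigError("no in-phase start fits on the target transcript")
            if self.phase_fidelity < 1 and not self.off_phase_starts():
                raise ConfigError("no off-phase start fits on the target transcript")
            if self.minus_strand_phased and self.cleavage.p0 < 2:
                raise ConfigError("minus-strand phased reads need p0 >= 2")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted with a simulated library: per-read labels and
    origins (aligned with the ReadSet's read order), realized class counts,
    and the generating config."""

    records: tuple[tuple[str, str, str, int, str], ...]  # id, class, ref, start, strand
    class_counts: dict[str, int]
    config: SimConfig

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(rec[1] for rec in self.records)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def simulate_library(config: SimConfig) -> tuple[ReadSet, SimTruth]:
    """Draw a library of ``n_reads`` labelled reads from the mixture.

    Deterministic given (config, seed): identical configs yield identical
    read sequences, order and truth records.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pre = config.precursor
    pre_seq = pre.ref.sequence
    guide, star = config.guide, config.star_seq
    classes = list(config.weights)
    probs = np.array([config.weights[c] for c in classes])
    labels = rng.choice(len(classes), size=config.n_reads, p=probs)

    jitter_cells = [cell for cell, _ in config.jitter]
    jitter_probs = np.array([p for _, p in config.jitter]) if config.jitter else None
    phase_pos = config.phase_position_list()
    off_pos = config.off_phase_starts()
    p0 = config.cleavage.p0
    tgt = config.target.sequence
    forbidden = (pre_seq, tgt)

    reads: list[tuple[str, int]] = []
    records: list[tuple[str, str, str, int, str]] = []
    counts = {c: 0 for c in CLASSES}

    for i, li in enumerate(labels):
        cls = classes[li]
        read_id = f"read{i + 1:06d}"
        if cls == "guide_accurate":
            seq, ref, start, strand = guide, pre.ref.ref_id, pre.guide_start, "+"
        elif cls == "guide_jitter":
            offset, length = jitter_cells[rng.choice(len(jitter_cells), p=jitter_probs)]
            s = pre.guide_start + offset
            seq, ref, start, strand = pre_seq[s : s + length], pre.ref.ref_id, s, "+"
        elif cls == "star":
            if pre.star_start is not None:
                ref, start, strand = pre.ref.ref_id, pre.star_start, "+"
            else:
                ref, start, strand = "", -1, "."
            seq = star
        elif cls == "degradation":
            length = int(rng.integers(_LEN_RANGE[0], _LEN_RANGE[1] + 1))
            s = int(rng.integers(0, len(pre_seq) - length + 1))
            seq, ref, start, strand = pre_seq[s : s + length], pre.ref.ref_id, s, "+"
        elif cls == "phased":
            in_phase = rng.random() < config.phase_fidelity
            s = int(
                phase_pos[rng.integers(0, len(phase_pos))]
                if in_phase
                else off_pos[rng.integers(0, len(off_pos))]
            )
            cls = "phased_in" if in_phase else "phased_off"
            as_minus = config.minus_strand_phased and rng.random() < 0.5
            if as_minus and s >= 2 and s + 19 <= len(tgt):
                # duplex partner of the (+) siRNA at s: forward interval [s-2, s+19)
                seq = revcomp(tgt[s - 2 : s + 19])
                ref, start, strand = config.target.ref_id, s - 2, "-"
            else:
                seq = tgt[s : s + 21]
                ref, start, strand = config.target.ref_id, s, "+"
        else:  # background
            while True:
                length = int(rng.integers(_LEN_RANGE[0], _LEN_RANGE[1] + 1))
                seq = _random_seq(rng, length)
                rc = revcomp(seq)
                if not any(seq in r or rc in r for r in forbidden):
                    break
            ref, start, strand = "", -1, "."
        counts[cls] += 1
        reads.append((seq, 1))
        records.append((read_id, cls, ref, start, strand))

    library = ReadSet(reads=tuple(reads), library_id=f"sim_seed{config.seed}")
    truth = SimTruth(records=tuple(records), class_counts=counts, config=config)
    return library, truth


# ---------------------------------------------------------------------------
# Closed-form expectations


def _class_support(config: SimConfig) -> Iterator[tuple[str, float, str | None]]:
    """Enumerate (class, probability, sequence) over the full generative
    support.  Probabilities sum to 1; background yields sequence None (its
    defining property is mapping nowhere)."""
    pre = config.precursor
    pre_seq = pre.ref.sequence
    tgt = config.target.sequence
    w = config.weights
    if w["guide_accurate"] > 0:
        yield "guide_accurate", w["guide_accurate"], config.guide
    if w["guide_jitter"] > 0:
        for (offset, length), p in config.jitter:
            s = pre.guide_start + offset
            yield "guide_jitter", w["guide_jitter"] * p, pre_seq[s : s + length]
    if w["star"] > 0:
        yield "star", w["star"], config.star_seq
    if w["degradation"] > 0:
        n = len(pre_seq)
        for length in range(_LEN_RANGE[0], _LEN_RANGE[1] + 1):
            per = w["degradation"] / 6.0 / (n - length + 1)
            for s in range(n - length + 1):
                yield "degradation", per, pre_seq[s : s + length]
    if w["phased"] > 0:
        phase_pos = config.phase_position_list()
        off_pos = config.off_phase_starts()
        fid = config.phase_fidelity
        for positions, share in ((phase_pos, fid), (off_pos, 1.0 - fid)):
            if share == 0 or not positions:
                continue
            per = w["phased"] * share / len(positions)
            for s in positions:
                if config.minus_strand_phased and s >= 2 and s + 19 <= len(tgt):
                    yield "phased", per / 2.0, tgt[s : s + 21]
                    yield "phased", per / 2.0, revcomp(tgt[s - 2 : s + 19])
                else:
                    yield "phased", per, tgt[s : s + 21]
    if w["background"] > 0:
        yield "background", w["background"], None


def truth_expectations(config: SimConfig) -> dict[str, object]:
    """Exact expected values of every pipeline statistic under the config.

    Computed by enumerating the generative support with its probabilities
    and passing each support sequence through the real mapping geometry —
    an expectation over the mixture, with no Monte Carlo involved.
    """
    config.validate()
    refs = [config.precursor.ref, config.target]
    pre_id = config.precursor.ref.ref_id
    tgt_id = config.target.ref_id
    anchor = config.precursor.expected_five_prime
    p0 = config.cleavage.p0
    lo, hi = _LEN_RANGE

    denom = 0.0
    cells: dict[tuple[int, int], float] = {}
    reg_total = 0.0
    reg1 = 0.0
    guide_prob = 0.0
    star_prob = 0.0
    for _cls, p, seq in _class_support(config):
        if seq is None:
            continue
        if seq == config.guide:
            guide_prob += p
        if seq == config.star_seq:
            star_prob += p
        for h in map_exact(ReadSet(((seq, 1),)), refs):
            if h.ref_id == pre_id and h.strand == "+" and lo <= h.length <= hi:
                denom += p * h.weight
                key = (h.start - anchor, h.length)
                cells[key] = cells.get(key, 0.0) + p * h.weight
            if h.ref_id == tgt_id and h.length == 21:
                if h.strand == "+" and h.start >= p0:
                    reg_total += p * h.weight
                    if (h.start - p0) % 21 == 0:
                        reg1 += p * h.weight

    gl = config.precursor.guide_length
    exact = cells.get((0, gl), 0.0) / denom if denom > 0 else math.nan
    windowed = (
        sum(v for (o, _l), v in cells.items() if abs(o) <= 4) / denom
        if denom > 0
        else math.nan
    )
    return {
        "denominator_share": denom,
        "exact_mature_fraction": exact,
        "windowed_accuracy": windowed,
        "cell_frequencies": {k: v / denom for k, v in cells.items()} if denom > 0 else {},
        "guide_rpm": 1e6 * guide_prob,
        "star_rpm": 1e6 * star_prob,
        "phased_qualifying_share": reg_total,
        "register1_proportion": reg1 / reg_total if reg_total > 0 else math.nan,
    }


# ---------------------------------------------------------------------------
# Study-condition reference and config builders


def default_jitter_table(
    spec: PrecursorSpec, extra_mass: dict[tuple[int, int], float] | None = None
) -> tuple[tuple[tuple[int, int], float], ...]:
    """A realistic imprecise-processing table: 5'-offsets in [-4, 4] decaying
    geometrically, mature length favoured over +/-1-nt length variants, the
    accurate cell excluded.  ``extra_mass`` pins absolute probabilities on
    chosen cells (e.g. an abundant alternative form); the default cells share
    the remainder."""
    gl, gs, n = spec.guide_length, spec.guide_start, len(spec.ref)
    extra = dict(extra_mass or {})
    raw: dict[tuple[int, int], float] = {}
    for offset in range(-4, 5):
        for length in range(max(19, gl - 1), min(24, gl + 1) + 1):
            cell = (offset, length)
            if cell == (0, gl) or cell in extra:
                continue
            if gs + offset < 0 or gs + offset + length > n:
                continue
            raw[cell] = 2.0 ** (-abs(offset)) * (1.0 if length == gl else 0.4)
    rest = 1.0 - sum(extra.values())
    if rest < 0:
        raise ConfigError("extra jitter mass exceeds 1")
    scale = rest / sum(raw.values())
    table = {**extra, **{cell: v * scale for cell, v in raw.items()}}
    return tuple(sorted(table.items()))


def make_study_references(
    ref_seed: int = 7, guide_length: int = 21, kind: str = "mir_foldback"
) -> tuple[PrecursorSpec, ReferenceSeq, TargetSite]:
    """Deterministic synthetic references emulating the study's constructs:
    a guide with a 5'U, its precursor (foldback or TAS-style transcript) and
    a target transcript carrying a perfectly complementary site."""
    rng = np.random.default_rng(ref_seed)
    guide = "T" + _random_seq(rng, guide_length - 1)
    star = derive_star(guide)
    if kind == "mir_foldback":
        flank5, loop, flank3 = _random_seq(rng, 30), _random_seq(rng, 48), _random_seq(rng, 30)
        seq = flank5 + guide + loop + star + flank3
        spec = PrecursorSpec(
            ref=ReferenceSeq("sim_foldback", seq, role="precursor"),
            kind="mir_foldback",
            guide_start=len(flank5),
            guide_length=guide_length,
            star_start=len(flank5) + guide_length + len(loop),
        )
    elif kind == "tas_transcript":
        flank5 = _random_seq(rng, 40)  # ends at the trigger-miRNA cleavage site
        d1 = _random_seq(rng, 21)      # 3'D1[+]; the guide occupies 3'D2[+]
        pad = 2 * 21 - guide_length    # keep downstream slots on the 21-nt grid
        tail = _random_seq(rng, pad + 60)
        seq = flank5 + d1 + guide + tail
        spec = PrecursorSpec(
            ref=ReferenceSeq("sim_tas", seq, role="precursor"),
            kind="tas_transcript",
            guide_start=len(flank5) + 21,
            guide_length=guide_length,
            trigger_cleavage_pos=len(flank5),
            phase_cycle=21,
        )
    else:
        raise ConfigError(f"unknown precursor kind {kind!r}")
    up, down = _random_seq(rng, 180), _random_seq(rng, 260)
    target = ReferenceSeq("sim_target", up + revcomp(guide) + down, role="transcript")
    site = TargetSite("sim_target", len(up), len(up) + guide_length, mismatches=0)
    return spec, target, site


def study_config(
    seed: int,
    *,
    n_reads: int = 50_000,
    accurate_fraction: float = 0.82,
    kind: str = "mir_foldback",
    guide_length: int = 21,
    background_share: float = 0.03,
    phased_share: float = 0.0,
    phase_fidelity: float = 0.394,
    minus_strand_phased: bool = False,
    jitter_extra: dict[tuple[int, int], float] | None = None,
    split: tuple[float, float, float] = (0.5, 0.2, 0.3),
    ref_seed: int = 7,
) -> SimConfig:
    """Build a study-condition config from the composition the statistics
    measure: ``accurate_fraction`` is the intended share of accurate guide
    reads among precursor-derived (+) reads; the remaining precursor share
    splits into jitter, star and degradation per ``split`` (5:2:3 by
    default)."""
    if abs(sum(split) - 1.0) > 1e-9:
        raise ConfigError("split must sum to 1")
    spec, target, site = make_study_references(ref_seed, guide_length, kind)
    precursor_share = 1.0 - background_share - phased_share
    if spec.star_start is not None:
        # foldback: the star is a (+)-strand precursor substring and counts
        # in the processing denominator
        w_acc = accurate_fraction * precursor_share
    else:
        # TAS: the star comes from the RDR6 dsRNA (-) strand and is excluded
        # from the (+) denominator; solve w_acc so the intended fraction is
        # met among denominator reads
        a, s = accurate_fraction, split[1]
        w_acc = a * precursor_share * (1.0 - s) / (1.0 - a * s)
    rest = precursor_share - w_acc
    config = SimConfig(
        seed=seed,
        n_reads=n_reads,
        precursor=spec,
        target=target,
        target_site=site,
        w_guide_accurate=w_acc,
        w_guide_jitter=split[0] * rest,
        w_star=split[1] * rest,
        w_degradation=split[2] * rest,
        w_phased=phased_share,
        w_background=background_share,
        jitter=default_jitter_table(spec, jitter_extra),
        phase_fidelity=phase_fidelity,
        minus_strand_phased=minus_strand_phased,
        require_5prime_u=True,
    )
    config.validate()
    return config


def write_truth(truth: SimTruth, path: str | Path) -> Path:
    """Write per-read truth records as TSV (read_id, class, ref, start, strand)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("read_id\tclass\tref\tstart\tstrand\n")
        for rec in truth.records:
            fh.write("\t".join(str(x) for x in rec) + "\n")
    return path
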