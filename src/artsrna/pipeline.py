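"""One-command orchestration: collapse -> map -> profile -> statistics -> report.

A run is described by a config file (YAML) naming the libraries, the
reference FASTA, the precursor annotation(s) and the target cleavage
geometry.  Statistics with a zero denominator are reported as "NA" — the
study's "no reads were observed" is a distinct state from a computed zero —
and the run continues.  Re-running a completed config is idempotent: report
bytes are identical and inputs are never mutated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ConfigError, UndefinedStatisticError
from .io import ReadFormat, ReadSet, ReportBundle, collapse, parse_reads, write_report
from .mapping import (
    Hit,
    PositionProfile,
    build_profile,
    map_exact,
    mapped_total,
    sequence_rpm,
)
from .phasing import phased_fraction, phasing_table
from .processing import classify_forms, exact_mature_fraction, processing_accuracy
from .reference import (
    CleavageSite,
    PrecursorSpec,
    ReferenceSeq,
    TargetSite,
    predict_cleavage,
)

log = logging.getLogger("artsrna")


@dataclass(frozen=True)
class LibraryConfig:
    library_id: str
    path: Path
    format: ReadFormat = "fasta"
    collapsed_sep: str = "-"


@dataclass(frozen=True)
class TargetConfig:
    transcript_id: str
    cleavage_pos: int | None = None
    site_start: int | None = None
    site_length: int | None = None

    def __post_init__(self) -> None:
        explicit = self.cleavage_pos is not None
        site = self.site_start is not None
        if explicit == site:
            raise ConfigError(
                f"target {self.transcript_id}: provide exactly one of "
                "cleavage_pos or (site_start, site_length)"
            )
        if site and self.site_length is None:
            raise ConfigError(f"target {self.transcript_id}: site_start requires site_length")


@dataclass
class RunConfig:
    libraries: list[LibraryConfig]
    references_fasta: Path
    precursors: list[dict]
    targets: list[TargetConfig]
    out_dir: Path
    rpm_denominator: str = "library_total"
    processing_window: int = 4
    phasing_cycle: int = 21
    phasing_strand_mode: str = "plus_only"

    def validate(self) -> None:
        if not self.libraries:
            raise ConfigError("libraries: at least one library required")
        for lib in self.libraries:
            if not lib.path.exists():
                raise ConfigError(f"libraries[{lib.library_id}].path: {lib.path} does not exist")
        if not self.references_fasta.exists():
            raise ConfigError(f"references: {self.references_fasta} does not exist")
        if self.rpm_denominator not in ("library_total", "mapped_total"):
            raise ConfigError(f"rpm_denominator: unknown mode {self.rpm_denominator!r}")


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    try:
        libraries = [
            LibraryConfig(
                library_id=str(entry.get("id", Path(entry["path"]).stem)),
                path=_resolve(entry["path"]),
                format=entry.get("format", "fasta"),
                collapsed_sep=entry.get("collapsed_sep", "-"),
            )
            for entry in raw["libraries"]
        ]
        targets = [
            TargetConfig(
                transcript_id=t["transcript_id"],
                cleavage_pos=t.get("cleavage_pos"),
                site_start=t.get("site_start"),
                site_length=t.get("site_length"),
            )
            for t in raw.get("targets", [])
        ]
        config = RunConfig(
            libraries=libraries,
            references_fasta=_resolve(raw["references"]),
            precursors=list(raw.get("precursors", [])),
            targets=targets,
            out_dir=_resolve(raw.get("out_dir", "artsrna_out")),
            rpm_denominator=raw.get("rpm_denominator", "library_total"),
            processing_window=int(raw.get("processing", {}).get("window", 4)),
            phasing_cycle=int(raw.get("phasing", {}).get("cycle", 21)),
            phasing_strand_mode=raw.get("phasing", {}).get("strand_mode", "plus_only"),
        )
    except KeyError as exc:
        raise ConfigError(f"missing config field: {exc.args[0]}") from exc
    config.validate()
    return config


def _load_references(config: RunConfig) -> tuple[list[ReferenceSeq], list[PrecursorSpec]]:
    precursor_ids = {p["ref_id"] for p in config.precursors}
    refs: list[ReferenceSeq] = []
    by_id: dict[str, ReferenceSeq] = {}
    for rec in SeqIO.parse(str(config.references_fasta), "fasta"):
        role = "precursor" if rec.id in precursor_ids else "transcript"
        ref = ReferenceSeq(rec.id, str(rec.seq).upper().replace("U", "T"), role=role)
        refs.append(ref)
        by_id[ref.ref_id] = ref
    specs = []
    for p in config.precursors:
        if p["ref_id"] not in by_id:
            raise ConfigError(f"precursors[{p['ref_id']}]: no such reference sequence")
        specs.append(
            PrecursorSpec(
                ref=by_id[p["ref_id"]],
                kind=p["kind"],
                guide_start=int(p["guide_start"]),
                guide_length=int(p["guide_length"]),
                star_start=None if p.get("star_start") is None else int(p["star_start"]),
                trigger_cleavage_pos=(
                    None
                    if p.get("trigger_cleavage_pos") is None
                    else int(p["trigger_cleavage_pos"])
                ),
                phase_cycle=int(p.get("phase_cycle", 21)),
            )
        )
    for t in config.targets:
        if t.transcript_id not in by_id:
            raise ConfigError(f"targets[{t.transcript_id}]: no such reference sequence")
    return refs, specs


def _cleavage_site(t: TargetConfig) -> CleavageSite:
    if t.cleavage_pos is not None:
        return CleavageSite(t.transcript_id, t.cleavage_pos)
    site = TargetSite(t.transcript_id, t.site_start, t.site_start + t.site_length)
    return predict_cleavage(site)


def _fmt(value: float | str) -> str:
    return value if isinstance(value, str) else f"{value:.10g}"


def analyze_library(
    lib: LibraryConfig,
    refs: Sequence[ReferenceSeq],
    specs: Sequence[PrecursorSpec],
    config: RunConfig,
) -> tuple[ReportBundle, list[tuple[str, str, str]]]:
    """Run the full per-library analysis; returns the report bundle and the
    (library, statistic, value) rows for the run-level summary table."""
    raw = parse_reads(lib.path, lib.format, library_id=lib.library_id,
                      collapsed_sep=lib.collapsed_sep)
    library = collapse(raw)
    log.info("%s: %d reads, %d unique after collapsing", lib.library_id,
             library.total_reads, len(library))
    rows: list[tuple[str, str, str]] = [
        (lib.library_id, "library_total", str(library.total_reads)),
        (lib.library_id, "unique_reads", str(len(library))),
    ]
    bundle = ReportBundle()
    bundle.summary["library_id"] = lib.library_id
    bundle.summary["library_total"] = library.total_reads
    bundle.summary["unique_reads"] = len(library)
    bundle.summary["rpm_denominator_mode"] = config.rpm_denominator

    if library.total_reads == 0:
        log.warning("%s: empty library; all statistics undefined", lib.library_id)
        rows.append((lib.library_id, "mapped_total", "NA"))
        bundle.summary["mapped_total"] = "NA"
        return bundle, rows

    hits = map_exact(library, refs)
    mt = mapped_total(hits, library)
    log.info("%s: %d hits, %d reads mapped", lib.library_id, len(hits), mt)
    rows.append((lib.library_id, "mapped_total", str(mt)))
    bundle.summary["mapped_total"] = mt
    profiles = build_profile(hits, library, denominator=config.rpm_denominator)
    denominator = (
        library.total_reads if config.rpm_denominator == "library_total" else mt
    )
    bundle.summary["rpm_denominator"] = denominator

    bundle.hits = pd.DataFrame(
        [
            (h.ref_id, h.strand, h.start, h.end, h.length, h.read_seq, h.count, h.weight)
            for h in hits
        ],
        columns=["ref_id", "strand", "start0", "end0", "length", "read_seq", "count", "weight"],
    )
    if profiles:
        bundle.profile = pd.concat(
            [p.table.assign(ref_id=p.ref_id)[["ref_id", "strand", "start0", "length",
                                              "count", "rpm"]]
             for p in sorted(profiles.values(), key=lambda p: p.ref_id)],
            ignore_index=True,
        )

    processing_frames, summary_rows, rpm_rows = [], [], []
    for spec in specs:
        cls = classify_forms(hits, spec)
        processing_frames.append(cls.to_frame().assign(ref_id=spec.ref.ref_id))
        for metric, window, length_filter in (
            ("exact_mature_fraction", 0, spec.guide_length),
            ("windowed_accuracy", config.processing_window, "any"),
        ):
            try:
                value = processing_accuracy(
                    cls,
                    window=window,
                    exact_length=length_filter if isinstance(length_filter, int) else None,
                )
                out = _fmt(value)
            except UndefinedStatisticError:
                log.warning("%s/%s: %s undefined (no qualifying reads)",
                            lib.library_id, spec.ref.ref_id, metric)
                out = "NA"
            summary_rows.append((spec.ref.ref_id, metric, window, str(length_filter), out))
            rows.append((lib.library_id, f"{spec.ref.ref_id}.{metric}", out))
        profile = profiles.get(spec.ref.ref_id)
        guide, star = spec.guide_sequence, spec.star_sequence()
        if profile is None:
            g_rpm, s_rpm = 0.0, 0.0
        else:
            g_rpm = sequence_rpm(hits, guide, profile)
            s_rpm = sequence_rpm(hits, star, profile)
        rpm_rows.append((spec.ref.ref_id, "guide", guide, _fmt(g_rpm)))
        rpm_rows.append((spec.ref.ref_id, "star", star, _fmt(s_rpm)))
        rows.append((lib.library_id, f"{spec.ref.ref_id}.guide_rpm", _fmt(g_rpm)))
        rows.append((lib.library_id, f"{spec.ref.ref_id}.star_rpm", _fmt(s_rpm)))
    if processing_frames:
        bundle.processing = pd.concat(processing_frames, ignore_index=True)
        bundle.processing_summary = pd.DataFrame(
            summary_rows, columns=["ref_id", "metric", "window", "length_filter", "value"]
        )
        bundle.strand_rpm = pd.DataFrame(
            rpm_rows, columns=["ref_id", "role", "sequence", "rpm"]
        )

    phasing_frames = []
    for t in config.targets:
        site = _cleavage_site(t)
        table = phasing_table(
            hits, site, cycle=config.phasing_cycle, strand_mode=config.phasing_strand_mode
        )
        phasing_frames.append(table.to_frame().assign(transcript_id=t.transcript_id))
        try:
            reg1 = _fmt(phased_fraction(table, 1))
        except UndefinedStatisticError:
            log.warning("%s/%s: no qualifying reads for phasing",
                        lib.library_id, t.transcript_id)
            reg1 = "NA"
        rows.append((lib.library_id, f"{t.transcript_id}.register1_proportion", reg1))
        rows.append((lib.library_id, f"{t.transcript_id}.phasing_n_reads",
                     _fmt(table.n_reads)))
    if phasing_frames:
        bundle.phasing = pd.concat(phasing_frames, ignore_index=True)
    return bundle, rows


def run_analysis(config: RunConfig) -> list[Path]:
    """Execute the full pipeline for every library; returns the file manifest."""
    config.validate()
    refs, specs = _load_references(config)
    log.info("loaded %d references (%d precursor annotations)", len(refs), len(specs))
    manifest: list[Path] = []
    all_rows: list[tuple[str, str, str]] = []
    for lib in config.libraries:
        bundle, rows = analyze_library(lib, refs, specs, config)
        manifest.extend(write_report(bundle, config.out_dir, prefix=lib.library_id))
        all_rows.extend(rows)
    summary = pd.DataFrame(all_rows, columns=["library", "statistic", "value"])
    dest = Path(config.out_dir) / "summary.tsv"
    summary.to_csv(dest, sep="\t", index=False, lineterminator="\n")
    manifest.append(dest)
    return manifest


# ---------------------------------------------------------------------------
# Recovery mode: simulate -> analyze -> compare against exact expectations


def estimate_statistics(library: ReadSet, sim_config) -> dict[str, float]:
    """Run the analysis stages on a (simulated) library and return the point
    estimates of the statistics truth_expectations predicts."""
    collapsed = collapse(library)
    refs = [sim_config.precursor.ref, sim_config.target]
    hits = map_exact(collapsed, refs)
    cls = classify_forms(hits, sim_config.precursor)
    out: dict[str, float] = {}
    try:
        out["exact_mature_fraction"] = exact_mature_fraction(cls)
        out["windowed_accuracy"] = processing_accuracy(cls, window=4)
    except UndefinedStatisticError:
        out["exact_mature_fraction"] = math.nan
        out["windowed_accuracy"] = math.nan
    out["denominator_share"] = cls.denominator / library.total_reads
    profiles = build_profile(hits, collapsed, denominator="library_total")
    profile = profiles.get(sim_config.precursor.ref.ref_id)
    if profile is None:
        out["guide_rpm"] = 0.0
        out["star_rpm"] = 0.0
    else:
        out["guide_rpm"] = sequence_rpm(hits, sim_config.guide, profile)
        out["star_rpm"] = sequence_rpm(hits, sim_config.star_seq, profile)
    table = phasing_table(hits, sim_config.cleavage, cycle=21, strand_mode="plus_only")
    out["phased_qualifying_share"] = table.n_reads / library.total_reads
    try:
        out["register1_proportion"] = phased_fraction(table, 1)
    except UndefinedStatisticError:
        out["register1_proportion"] = math.nan
    return out


def recovery_table(sim_config, library: ReadSet | None = None) -> pd.DataFrame:
    """Estimates vs exact expectations with 3-binomial-SD bounds.

    Fractions are conditional on their qualifying-read subset, so the bound
    uses the expected qualifying count as the effective n; RPM statistics are
    per-library-read binomials on the RPM scale.
    """
    from .simulate import simulate_library, truth_expectations

    if library is None:
        library, _ = simulate_library(sim_config)
    expected = truth_expectations(sim_config)
    estimates = estimate_statistics(library, sim_config)
    n = library.total_reads

    def _bound(p: float, n_eff: float, scale: float = 1.0) -> float:
        if not 0.0 <= p <= 1.0 or n_eff <= 0 or math.isnan(p):
            return math.nan
        return scale * 3.0 * math.sqrt(p * (1.0 - p) / n_eff)

    n_denom = expected["denominator_share"] * n
    n_phased = expected["phased_qualifying_share"] * n
    rows = []
    for name, n_eff, scale in (
        ("denominator_share", n, 1.0),
        ("exact_mature_fraction", n_denom, 1.0),
        ("windowed_accuracy", n_denom, 1.0),
        ("guide_rpm", n, 1e6),
        ("star_rpm", n, 1e6),
        ("phased_qualifying_share", n, 1.0),
        ("register1_proportion", n_phased, 1.0),
    ):
        exp_val = expected[name]
        est_val = estimates[name]
        p = exp_val / scale if not (isinstance(exp_val, float) and math.isnan(exp_val)) else math.nan
        bound = _bound(p, n_eff, scale)
        both_nan = (
            isinstance(exp_val, float) and math.isnan(exp_val)
            and isinstance(est_val, float) and math.isnan(est_val)
        )
        diff = math.nan if both_nan else abs(est_val - exp_val)
        within = both_nan or (not math.isnan(bound) and diff <= bound)
        rows.append((name, est_val, exp_val, diff, bound, within))
    return pd.DataFrame(
        rows, columns=["statistic", "estimate", "expectation", "abs_diff", "bound_3sd",
                       "within_bound"]
    )
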