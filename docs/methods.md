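# Methods

## Scope and model

`artsrna` quantifies three aspects of artificial small RNA (art-sRNA)
experiments from small RNA-seq libraries: precursor processing fidelity,
guide/star duplex accumulation, and phasing of target-derived secondary
siRNAs. The underlying biological model:

* An **amiRNA precursor** is a miRNA-type foldback; DCL1 excises the mature
  guide at an annotated position. Imprecise processing produces reads whose
  5′ end is shifted and/or whose length deviates from the mature form.
* A **syn-tasiRNA precursor** is a TAS-type transcript cleaved by a trigger
  miRNA/AGO complex; RDR6 converts a fragment to dsRNA, and DCL4 dices it in
  21-nt increments phased with the trigger cleavage site. The guide occupies
  a phased slot (3′D2[+] in the emulated constructs), so its expected 5′ end
  is a whole number of 21-nt cycles downstream of the trigger cut.
* An art-sRNA of length *L* bound to its target guides AGO cleavage between
  the target nucleotides paired to sRNA positions 10 and 11; the 3′ fragment
  begins at p₀ = site_start + *L* − 10. Transitivity (typically triggered by
  22-nt sRNAs) yields 21-nt siRNAs whose 5′ ends are congruent to p₀
  modulo 21 ("register 1").

## Pipeline conventions

* Coordinates are 0-based, half-open, with the (+) strand of each reference
  as the frame; (−)-strand hits are reported on the forward coordinates of
  the matched interval so that profiles, processing offsets and phasing
  registers share one coordinate system. Report writers may add 1-based
  columns for display but the computational layer never mixes conventions.
* Mapping is exact: no mismatches, no gaps, both strands, every occurrence.
  A read with *k* hit positions within one reference carries weight 1/*k*
  at each, so weighted counts conserve read counts per reference. Reads
  containing N are retained through parsing but can never produce a hit.
* RPM = 10⁶ × weighted count / denominator. The denominator defaults to the
  library's total clean reads because it is stable under the choice of
  references; "total mapped reads" is available as a config switch since
  either reading of the common "RPM mapped reads" phrasing is defensible
  when only two references are mapped. Both totals are recorded in the run
  summary so results under either convention are auditable.
* Processing accuracy is computed in two framings that answer different
  questions: the *exact mature fraction* (5′ offset 0 and the exact mature
  length — on the precursor this cell is precisely the guide sequence) and
  the *windowed accuracy* (|offset| ≤ 4 nt, any length in 19–24). Both are
  always reported; the denominator is all 19–24-nt (+)-strand precursor
  reads. (−)-strand reads never enter the numerator or denominator.
* Phasing registers count 21-nt (+)-strand target reads with start ≥ p₀;
  reads upstream of or straddling the cut are excluded. An optional
  both-strand mode adds (−) reads with the canonical 2-nt duplex-overhang
  correction ((start + 2 − p₀) mod 21) and admits starts down to p₀ − 2
  (the duplex partner of an in-phase (+) siRNA begins there); it exists for
  simulator validation and is off by default.
* A ratio whose denominator is zero raises `UndefinedStatisticError`; the
  pipeline writes it as `NA` with a log line. "No qualifying reads were
  observed" is deliberately distinct from a computed 0.

## Star-strand derivation

When the precursor annotation includes the star position, the annotated
substring is used (real foldbacks contain mismatches, so annotation beats
derivation). Otherwise the star is the duplex partner under perfect
complementarity with 2-nt 3′ overhangs: revcomp(star)[i] = guide[i + 2],
with the two unconstrained star bases taken from the precursor context when
the guide's downstream flank exists, else as complements of the guide's
first two bases. For TAS precursors this puts the star on the dsRNA (−)
strand, so star reads map antisense to the precursor and do not enter the
(+)-strand processing denominator — which matters for calibrating simulated
compositions (below).

## Synthetic data generator

A simulated library draws `n_reads` class labels from a mixture and emits
one sequence per read, with the label, origin and strand recorded as ground
truth:

| class | emission |
|---|---|
| guide_accurate | the exact guide substring |
| guide_jitter | precursor substring at (guide_start + offset, length) drawn from a jitter probability table over offsets [−4, 4] × lengths 19–24, excluding the accurate cell |
| star | the star sequence |
| degradation | uniform random (+)-strand precursor substring, length uniform in 19–24 |
| phased | 21-nt target substring downstream of p₀, starting on a phase position with probability `phase_fidelity` (uniform over the ladder), else uniform over off-phase downstream starts |
| background | random 19–24-mer rejection-sampled to be absent from every reference on both strands, so "unmapped" is a verifiable truth label |

Off-phase support excludes in-phase positions, making the register-1
expectation exactly fidelity-driven. With `minus_strand_phased`, half of
the phased reads are emitted as the (−)-strand duplex partner (forward
start s − 2). Identical configs give byte-identical libraries.

`truth_expectations` computes the exact expectation of every statistic by
enumerating the finite generative support with its probabilities and
passing each support sequence through the real mapping geometry — an exact
mixture expectation, not a Monte Carlo estimate — including second-order
effects such as degradation fragments that happen to equal the guide or to
multi-map. Recovery tests compare pipeline estimates against these
expectations with 3-binomial-SD bounds on the appropriate effective n
(e.g. the expected count of denominator reads for processing fractions).

### Default study conditions

`study_config` builds mixtures from the composition the statistics measure:
`accurate_fraction` (default 0.82) is the intended share of accurate guide
reads among (+)-strand precursor-derived reads; the remaining precursor
share splits 5:2:3 into jitter, star and degradation; background defaults
to 0.03 and transitivity (`phased_share`) to 0. Because the TAS star is
antisense and therefore outside the (+) denominator, the builder solves
w_accurate = a·P·(1−s)/(1−a·s) for TAS precursors (a = intended fraction,
P = precursor share, s = star split) so the intended fraction is met among
denominator reads. Default `phase_fidelity` is 0.394, the register-1 share
observed in the transitive regime the package emulates. The default jitter
table decays geometrically in |offset| and favours the mature length over
±1-nt variants — a generic imprecise-processing shape, not a fit to any
particular library; `jitter_extra` can pin absolute mass on chosen cells
(used for regimes dominated by one alternative form, e.g. an abundant
same-start 21-nt form from a 22-nt precursor).

Synthetic references are deterministic given `ref_seed`: a guide with the
canonical 5′U, a foldback (flank–guide–loop–star–flank) or TAS transcript
(trigger site at the 5′ flank boundary, D1 slot, guide at D2), and a target
transcript carrying the perfectly complementary site.

### What the simulator does not emulate

Sequencing errors, adapter/quality artefacts, ligation or size-selection
biases (library protocols are known to bias length distributions, but no
quantitative model is available), RNA secondary structure, G:U wobble
pairing, and genome-scale multi-locus mapping ambiguity. Passing recovery
tests therefore demonstrate the correctness of the statistics under the
stated mixture model, not robustness to these real-data artefacts.

## Numerical and design choices

* Mixture weights and jitter tables must sum to 1 within 1e−9; jitter cells
  that would exceed precursor bounds fail validation rather than being
  silently skipped.
* Collapsing orders unique sequences lexicographically; hit tables are
  sorted by (ref, start, strand, sequence); report floats use `%.10g`; no
  timestamps are written — together these make every output byte-stable.
* Palindromic reads matching both strands at one interval are reported on
  both, sharing weight; this is consistent with the per-reference weight
  normalization.
* `find_target_site` uses plain Hamming comparison against the reverse
  complement of the sRNA (no gaps, no G:U awareness): the emulated
  art-sRNAs are designed near-perfectly complementary, and the mapper
  itself is exact.
* Phase ladders truncate starts that cannot hold a full cycle-length sRNA
  on the transcript.
* Adapter and quality trimming are out of scope: the pipeline consumes
  clean reads, and FASTQ qualities are ignored.

## Problem sizes

The test suite and the reproduction script use simulated libraries of
50,000 reads for recovery checks (5 seeds per processing regime, 3 per
phasing regime), 200 random library/reference pairs (references up to
2 kb) for mapper-oracle equivalence, and 100 random libraries for count
conservation. At these sizes the 3-SD recovery bounds are a few percentage
points wide, comfortably separating the emulated regimes (20 % vs 65 % vs
82 % accuracy; phase fidelity 0 vs 0.4 vs 1).

## Known limitations

* Real libraries contain endogenous sRNAs that map to the target transcript
  independently of transitivity; the simulator's background is deliberately
  unmappable, so target-mapping noise floors must be judged from real data.
* The exact-mapping contract means a single sequencing error drops a read
  entirely; accuracy estimates from real data are therefore conditional on
  upstream cleaning quality.
* Multi-hit weighting (1/k) is a convention; the emulated references are
  short enough that multi-mapping is rare, but repeat-rich precursors would
  make the choice material.
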