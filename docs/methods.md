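# Methods

This note documents the models implemented in `mgsim`, the choices made
where the design was genuinely open, and what the synthetic test
fixtures do and do not demonstrate about real sequencing data.

## Conventions

Coordinates are 0-based, half-open throughout; the only conversion to
SAM's 1-based `POS` happens inside `seq_io`. Sequences are uppercase
A/C/G/T/N; `U` maps to `T` and all other IUPAC ambiguity codes collapse
to `N` on input, which keeps the 4-letter substitution model
well-defined. Each FASTA record is its own simulation unit —
multi-replicon genomes are *not* concatenated, so no read can span an
artificial junction. Quality scores are PHRED integers in [0, 62]
(the printable range at ASCII offset 64); FASTQ offsets are 33 or 64,
paired by convention with the 454 and Illumina platforms respectively
but overridable everywhere.

## Composition estimation

Reads are grouped by id across all their alignment records (primary and
secondary). A read whose hits all fall on one genome is *unique*, even
if it hits several positions there. Weighted sharing of multi-mapped
reads uses the per-base unique-read density `m_i / s_i`; the
pseudo-count (default 0.001) enters `m_i`, not the ratio, so genomes
with no unique evidence split a shared read by inverse genome size.

The sharing is deliberately **two-pass**: `m_i` is frozen at the
unique-read counts before any multi-mapped read is distributed. An
online update (each shared read changing the weights of the next) would
make the result depend on the order reads appear in the SAM file; the
two-pass form is deterministic and order-free.

The candidate threshold (default 10 reads) is a strict `>` comparison.
Estimated abundances are normalized *read-count shares*. Note the
asymmetry with simulation, where expected read numbers are proportional
to abundance × genome size: a composition estimated from reads and fed
back into the simulator reproduces the original *read flow* only when
genome sizes are equal (as they are in the test fixtures) or when the
user converts shares to per-cell abundances by dividing by genome size.
This mirrors the convention of the estimation procedure the module
implements; it is documented rather than silently "fixed".

## Error model

* `p = 10^(-q/10)` (standard PHRED, log base 10).
* Per-cycle quality distributions are full histograms over scores 0–62.
  Estimation divides score counts at cycle `c` by the number of reads
  covering `c`, so ragged read lengths are handled; cycles beyond the
  estimation depth reuse the last estimated cycle.
* Error-type counting walks CIGAR (I/D bases) and the MD string
  (mismatch letters) against the read sequence to obtain
  (reference base → read base) substitution pairs. Soft-clipped bases
  are excluded everywhere: they are not aligned evidence. Records
  without MD contribute indel counts only. MD/CIGAR inconsistencies
  raise with the read id rather than being skipped.
* The substitution matrix is stored as a **joint** distribution over
  the 12 ordered pairs (the 454 default's entries sum to 1 across the
  whole table, not per row); simulation renormalizes the row of the
  actual template base into a conditional. Row/column orientation:
  rows are the original (template) base.
* Platform defaults when no errors are observed: proportions
  (ins, del, sub) = (0.01, 0.005, 0.985) for Illumina and
  (0.2, 0.15, 0.65) for 454; the 454 default substitution matrix is a
  published pyrosequencing profile, while the Illumina default is a
  *neutral uniform* matrix over the 12 pairs — it is not data-derived,
  and any real use should estimate a matrix with
  `estimate_error_model`.
* `ErrorModel.platform_default` also needs a quality profile to be
  runnable without data. The shipped profile is synthetic: per-cycle
  discretized normals with the mean falling linearly from 34 to 20
  across the read and sd 3 — a generic quality-decay shape, chosen once
  and not tuned. Everything the tests assert about error rates is
  relative to the model-implied expectation, so this choice sets the
  regime (≈0.38 errors per 100-bp read), not the correctness criteria.

## Coverage bias

Genomes are cut into `interval_size` (default 100 bp) windows with a
0.1 pseudo-count. A read is binned by its leftmost coordinate only (the
SAM convention for both strands), not spread over the windows it
overlaps — self-consistent with position sampling, which also works at
start-coordinate granularity.

Biased sampling draws an interval with probability ∝ weight, then a
start uniformly within the interval, then clamps the start so the read
fits (`start + length ≤ genome size`). Clamping, rather than wrapping,
means genomes are treated as linear; it slightly over-weights the last
valid window (the final `length − 1` candidate starts fold onto
`size − length`). When *no* profile is supplied the simulator draws
starts uniformly over the whole valid range directly — the uniform path
is exact, not a uniform-weight profile.

A profile is keyed to the genome (and length) it came from; applying it
to a different genome is an error, never a rescale.

## Simulation

Draw order is fixed and documented, so one seed gives byte-identical
FASTQ: (1) multinomial allocation of the read budget with probabilities
∝ abundance × size; (2) per genome, a batch of lengths, then start
positions, then strands; (3) per read, per-cycle quality and error
draws. Strands are equiprobable.

Error injection walks cycles: draw `q`, err with `10^(-q/10)`, pick the
type from the proportions. Substitutions always change the base (zero
diagonal); on an `N` template base a uniform random base is emitted and
`N` is never a substitution target. Insertions emit a uniform random
base without consuming template. A deletion consumes a template base
and *re-attempts the same cycle* (same `q`, fresh error draw), so every
cycle eventually emits exactly one base and read length always equals
the requested length — FASTQ consumers get `len(seq) == len(qual)`
unconditionally. To feed deletions, the template window is over-fetched
by `max(10, 0.2·length)` bases (leftward for minus-strand reads); a
read that still exhausts its template — possible only near a genome
end under extreme error rates — is regenerated at a fresh position and
counted in a log message.

The expected errors per read implied by a model is
`Σ_c E_q[p(q) / (1 − p(q)·p_del)]`: the deletion re-attempt inflates
the per-cycle error count geometrically, and the correction is averaged
over the score distribution (it is convex in `p`, so applying it to the
mean probability would bias low).

Paired mode draws a fragment length from Normal(insert mean, sd),
rounds, clamps into [max mate length, genome size], places the fragment
like a read, and reads the two ends inward: mate 1 from the fragment's
5′ end, mate 2 from the other end on the opposite strand. The insert
model being normal is a package choice; nothing downstream depends on
its shape.

Read ids are `MGSIM|genome|start|end|strand|serial[/1|/2]` with
`start`/`end` the reference bases actually covered (leftmost-based,
half-open). This provenance makes closed-loop tests mapper-free.

Each read additionally records its edit list (op, template offset,
cycle, reference base, read base). `evaluation.true_alignments`
rebuilds exact CIGAR/MD/NM from it — counts alone could not — so the
error-model estimator can be validated against alignments that encode
precisely the injected errors. These alignments are emitted in read
orientation (the reference is the oriented template): error counts and
substitution pairs are defined in that frame, and nothing downstream of
them consults the start coordinate. `evaluation.oracle_alignments` is
the simpler all-M variant used where only the read's origin matters
(composition, coverage).

## Fidelity metrics

`bc_distance` aligns labels, normalizes both vectors to sum 1 and
applies Bray–Curtis (via `scipy.spatial.distance.braycurtis`); on
normalized input it equals half the L1 distance, which the tests
cross-check. Normalizing first makes the metric scale-invariant — raw
count comparisons must opt in by pre-scaling. `coverage_compare`
reports BC on normalized weights and Pearson r on raw weights
(normalization cancels under Pearson), optionally truncated to the
first *n* intervals.

## Synthetic fixtures: what they show and what they do not

`make_fixture` generates i.i.d. genomes at a requested GC content with
three community presets: LC (2 genomes, 0.9/0.1), MC (9 genomes in 5
abundance levels, two dominant: 0.25, 0.25, 0.12, 0.12, 0.08, 0.08,
0.04, 0.04, 0.02) and HC (11 genomes, equal abundance). The MC level
values are a package choice within the "9 genomes / 5 levels / 2
dominant" structure. Optional coverage profiles are sinusoidal,
`w = 1 + A·sin(2πi/period)` (A = 0.8, period 20 intervals), giving a
smooth, strongly non-uniform truth for bias-recovery tests.

I.i.d. genomes contain essentially no shared sequence, so closed-loop
tests here exercise the *machinery* (weighting, binning, MD
bookkeeping, normalization) under clean identifiability: 100-bp reads
from 100-kbp random genomes map back uniquely ≥ 99.9% of the time by
exact substring search. Real communities share operons, rRNA loci and
mobile elements; multi-mapping is then common, composition estimates
inherit the mapper's ambiguity handling, and coverage bias correlates
with GC and origin distance rather than a sinusoid. Passing the suite
therefore demonstrates correctness of the algorithms, not that a
particular real dataset will be matched without estimating its models
first.

## Problem sizes and numerical choices

The benchmark computations use: 150,000 error-free 100-bp reads
(11 × 100 kbp HC community) for self-mapping; 30,000 reads for the
errors-per-read check (a sample-SEM 3σ criterion is scale-free);
100,000 reads (1 × 100 kbp genome, sinusoidal bias) for error-model
and coverage recovery; 50,000 reads (MC community) for composition
recovery. These sizes put sampling error comfortably below the
assertion thresholds (e.g. total variation < 0.02 per cycle at
100,000 reads) while the whole suite stays in the low minutes on one
CPU.

Other numerics: per-cycle distributions must sum to 1 within 1e-9;
the substitution matrix within 1e-4 (published tables are printed to 5
decimals); compositions renormalize on construction; zero-mass
substitution rows fall back to uniform-over-three; quality scores are
capped at 62.

## Known limitations

* No homopolymer-length-dependent indel model for 454-style data, no
  SNP/variant simulation, no amplicon/PCR model.
* Coverage bias is an explicit empirical distribution, not a
  GC-parametric model; it cannot extrapolate to genomes without
  alignment data.
* The >200-bp re-alignment adjustment some pipelines apply before
  error counting is out of scope; alignments are consumed as given.
* Composition estimation is a single weighted pass, not an EM
  iteration; heavily shared references will blur abundances.
* Reads never wrap origins (no circular genomes).
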