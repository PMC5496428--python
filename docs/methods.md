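# Methods

## The normalization model

Digital normalization treats an assembler's input as redundant once
every k-mer of a read has been observed about *A* times. The filter
maintains approximate k-mer abundances in a count-min sketch (CMS) and
makes a streaming, single-pass accept/reject decision per read; only
accepted reads are counted, so abundances reflect the *output* stream
and acceptance self-limits near the target.

Two rules are implemented.

**bignorm (quality-gated count-vector rule).** The read's k-mer
windows are classified: *valid* windows contain no N; *high-quality*
windows are valid and every base reaches the phred threshold Q₀. The
sketch is queried for the high-quality windows only, and the read is
accepted iff at least `n_min` of those counts are `< A`. Two
consequences follow from the construction: reads whose quality has
collapsed (no window passes Q₀) are rejected regardless of novelty, so
the surviving set has a mean phred at or above the input's; and
erroneous k-mers — which are mostly unique — cannot rescue a read
unless at least `n_min` of them pass the quality gate, which is what
`n_min > 1` is for.

**diginorm (median rule).** For comparison, the classic rule: accept
iff the median k-mer count is `< A`. It is intentionally reproduced
together with its two known defects — quality blindness, and the
coercion of N to A before counting, which credits k-mers that were
never sequenced. The package's N handling in bignorm mode instead
drops every window that overlaps an N, from both the decision and the
insertion; this is equivalent to counting the N-free segments of the
read separately (a unit test asserts exactly that identity).

**Admission policy.** On acceptance, all valid windows are inserted,
not only the high-quality ones: quality gates *evidence of novelty*,
but the abundance bookkeeping should reflect everything a downstream
assembler will see. Inserting only high-quality windows is available
via `insert_hq_only` / `--insert-hq-only`.

**Pairing.** Mates are judged independently by default. The
`either-mate-rescues` policy keeps a pair in full when either mate is
accepted (and then counts both mates), avoiding orphaned mates for
paired-aware assemblers at the cost of a slightly higher keep rate.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `k` | 20 | bases | standard for bacterial-scale normalization; 4^20 ≫ genome size keeps random k-mer collisions negligible |
| `q0` | 20 | phred | recommended operating point; phred 20 = 1% error probability |
| `abundance` (A) | 20 | counts | the usual normalization target; well below the 255 counter cap |
| `n_min` | 3 | k-mers | heuristic; 1 = "any novel evidence", larger values demand corroboration and suppress error-driven acceptance |
| `cms m` | 1024 (CLI) / 4 (library tests) | MiB per table | m=1024, t=10 is the 10 GiB production sizing; 1-byte counters, width w = m·2²⁰ |
| `cms t` | 10 (CLI) / 4 | tables | more tables tighten the one-sided error; t·m MiB total |
| `seed` | 42 | — | seeds the hash family; identical seeds give identical sketches across platforms |

Counters saturate at 255. Since every decision threshold in practical
use sits near A ≈ 20, saturation can never flip a decision; it only
caps reporting.

## Hashing

Row indices are `mix64(code XOR row_key) mod w`, where `mix64` is a
splitmix64-style 64-bit avalanche finalizer and the `row_key`s are
derived from the user seed by the same mix over a Weyl sequence. The
mix is bijective on 64-bit words, so distinct canonical codes collide
only through the `mod w` reduction; a chi-square test in the suite
checks bucket uniformity. `w` need not be prime — avalanche mixing
removes the need for prime moduli. Determinism across runs and
platforms is part of the contract and is tested.

## The simulator

The generator emulates the features of MDA single-cell libraries that
matter to a coverage-normalizing filter:

* **Coverage skew** — the genome is tiled into 1 kb blocks, each block
  receives a lognormal amplification weight `exp(N(0, σ²))`, and read
  start positions are drawn proportional to their block's weight.
  σ = 2 (default) produces max/mean per-base coverage ratios of one to
  two orders of magnitude at 200× mean, the regime reported for real
  MDA data; σ = 0 recovers uniform shotgun sampling. The block model is
  the simplest mechanism with a single knob that produces the
  phenomenon; it is not a mechanistic model of MDA chemistry.
* **Quality decline** — per-base phred scores follow a linear profile
  from `q_start` (default 38) to `q_end` (default 20) plus Gaussian
  jitter (sd 3), rounded and clamped to [2, 41] (the Illumina 1.8+
  range). Near the clamp boundaries the truncation biases the realized
  mean slightly toward the interior; tests of the profile's linearity
  therefore use profiles ≥ 3 jitter sd away from the clamps.
* **Errors** — each base is substituted with probability 10^(−q/10)
  at its assigned phred q, so the low-quality read tail is genuinely
  error-rich, and the error k-mer spectrum has the low-abundance
  signature that makes `n_min` meaningful. Indels, chimeras and
  adapter sequence are *not* modeled: the filter is k-mer-count based
  and substitutions already produce the relevant erroneous-k-mer
  regime. A fraction `n_rate` (default 10⁻³) of bases is masked to N
  (carrying the floor quality 2).
* **Ground truth** — every read records its pre-error origin interval,
  and coverage statistics are computed exactly from those intervals
  rather than by remapping with an aligner. This is the one deliberate
  substitution relative to an alignment-based evaluation pipeline: it
  removes the aligner as a dependency and makes the coverage statistic
  exact, at the cost of not exercising mapping ambiguity.

Because reads are i.i.d. given the weight field and errors are
substitution-only, passing tests demonstrate the filter's counting and
decision logic, not robustness to structural artifacts (chimeras,
adapter read-through, GC-dependent amplification) present in real
single-cell data.

## Numerical and convention choices

* **Canonical k-mers**: the numeric minimum of the 2-bit forward code
  and its reverse complement; strand-independent counting.
* **Median**: the *lower* median (⌈n/2⌉-th order statistic), so the
  decision value is always an attained count; thresholds are strict
  (`< A`).
* **Percentiles**: nearest-rank over *all* genome positions including
  zeros — P10 is meant to detect starved loci, which dropping zeros
  would hide.
* **Degenerate inputs**: reads shorter than k are rejected
  (`TOO_SHORT`); reads with zero high-quality windows are rejected
  (`NO_ASSESSABLE_KMERS`); an empty input yields 0/0 reads with
  `percent_kept` defined as 0 and mean phred reported as null.
* **FASTQ**: strict 4-line Sanger phred+33 only. A file whose first
  record's quality characters all exceed `'J'` (phred 41) is rejected
  as likely phred+64 rather than silently mis-decoded; a legitimate
  Sanger file with *every* first-record base above phred 41 would trip
  this heuristic — accepted as a safe false positive.
* **k ≤ 31** so codes fit 64 bits.

## Problem sizes

The test-suite and acceptance-script simulations use 100 kb genomes
with 200 000 reads of 100 bp (200× mean coverage) for end-to-end
coverage properties, 10⁴ reads for exact-counter equivalence runs, and
MiB-scale sketches (m = 4–16, t = 4–6). These sizes put every
statistic well inside its asymptotic regime for a k-mer filter —
coverage-per-locus distributions and acceptance dynamics depend on
coverage depth and k-mer uniqueness, both of which are preserved —
while keeping any single run under a few minutes on one core.

## Known limitations

* The bignorm count-vector criterion is parameterized by `n_min`,
  which is a heuristic; no ground-truth value exists for it, and it is
  deliberately surfaced as a flag rather than buried.
* Whether quality should gate insertion (not just decision) is
  genuinely open; both policies are implemented, defaulting to
  quality-free insertion.
* The sketch offers no serialization-format stability, no conservative
  update, and no disk backing.
* Paired-end simulation emits mates as independent draws of the same
  locus, not as insert-size-accurate fragments.
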