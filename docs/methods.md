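# Methods

## Read processing and clone tallying

Input is merged amplicon reads (FASTA/FASTQ, optionally gzipped), one file
per (sorting round, sequencing replicate), declared in a YAML manifest
together with the amplicon layout: a six-residue anchor, the expected
translated length, the 0-based indices of the mutated positions, and a
per-sample reading-frame offset (library preparations often stagger
samples by single bases to decorrelate flow-cell signal; the offset is
configuration, never auto-detected, so results are deterministic).

Each read is translated from its frame offset with the standard genetic
code. Reads are rejected before any other check when a codon contains `N`
or a stop codon falls inside the expected coding span — such reads cannot
yield a valid mutation string. A translated read is kept iff its length
equals the expected length and its first six residues match the anchor
with at most one mismatch; the remainder of the read is deliberately not
compared to a template, so novel framework variants do not bias the tally.
The residues at the mutated positions are concatenated into the clone's
*mutation string* and counted exactly. Because amplicon pools contain few
distinct sequences, per-read outcomes are memoised on the nucleotide
string; a 10⁶-read sample tallies in seconds.

Replicate merging offers two filters: *common-any-round* keeps clones seen
in all replicates of at least one round (the permissive set used to build
matrices); *common-required-rounds* keeps clones seen in all replicates of
every listed early round while allowing absence in the terminal round (the
stricter set that is scored — a clone may legitimately drop out of the
last sort). Per-round clone frequency is the mean over replicates of
count / total QC-passing reads of that replicate, with absent observations
contributing zero. Frequencies therefore have read-abundance semantics
(the wild type's is ~0.92, not 1/n-clones).

## Matrices

Per round, the count matrix accumulates each clone's replicate-summed
observations at every mutated position (sums, not averaged frequencies:
matrices need integers, and the replicate-averaged frequencies are
reserved for the clone-level comparator metrics). The probability matrix
adds a pseudocount of √N to *every* cell — N being the round's total
observations — and normalises each position by N + 20·√N, so all entries
are strictly positive and no log-score is infinite. We read "add
pseudocounts to each amino acid at every position" literally; dividing √N
across the alphabet instead would shrink all scores toward the background
by a near-constant offset and leave clone *rankings* essentially
unchanged, which is why the literal reading is safe to fix once. The PSSM
is log2(PPM / b) with uniform background b = 0.05 (1/20); the PSERM is the
elementwise difference of two consecutive-round PSSMs, in which both the
background and the dominant wild-type signal cancel. Matrices are stored
with rows in fixed alphabetical residue order and 1-based position
columns, and serialise to TSV with a small header block (round, N,
pseudocount, background).

## Selection

A clone's score under a PSERM is the sum of its residues' entries over the
L positions. Rankings are descending with a lexicographic tie-break (the
all-zero-matrix degenerate case is therefore deterministic). Clones whose
value for a metric is undefined — enrichment ratios with a zero numerator
or denominator frequency — are excluded from that metric's ranking rather
than imputed; inventing a pseudo-frequency would manufacture extreme
ratios for exactly the rare clones the method cares about. The default
pipeline keeps the wild type when building matrices but excludes it from
rankings; both behaviours are flags. The final set is the top-K (default
K = 40) overlap of the two PSERMs minus clones with a cysteine at any
mutated position (the scaffold's paired cysteines lie outside the mutated
sites, so any such cysteine is unpaired — a developability liability).

Comparator metrics for benchmarking: terminal-round frequency, global
enrichment ratio log2(f_terminal / f_early) and local enrichment ratio
log2(f_terminal / f_prior), computed from the replicate-averaged
frequencies.

### Net charge

Net charge of a CDR fragment is the Henderson–Hasselbalch sum over
ionizable side chains: +1/(1+10^(pH−pKa)) for R, K, H and
−1/(1+10^(pKa−pH)) for D, E, C, Y. Default pKa set: D 3.65, E 4.25,
H 6.00, C 8.30, Y 10.07, K 10.53, R 12.48; pH 7.4. Termini are off by
default because CDRs are internal stretches. Published six-CDR totals
depend on the CDR definition and pKa table used, neither of which is
standardised, so tests assert only signs of individual loops, not totals.

## The synthetic campaign generator

The generator produces the data-generating process the pipeline consumes,
with ground truth:

* **Library.** The wild type at fraction 0.92 plus `n_variants` (default
  5000) distinct strings whose residues are drawn independently per
  position from the NNK codon amino-acid marginals (3/31 for L/R/S, 1/31
  for M/W, etc.; the single NNK stop codon TAG excluded and renormalised).
  The remaining 8% of mass is split by a symmetric Dirichlet(0.3), giving
  a long tail of variants down to ~10⁻⁶ and below.
* **Fitness.** Additive log-fitness: w(s) = exp(Σ_j e[s_j, j]), wild-type
  residues fixed at effect 0 so w(WT) = 1. Effects are drawn
  Normal(−0.05, 0.3): most mutations mildly deleterious, a minority
  beneficial. The mean was set, before any benchmark was run, by requiring
  the deterministic wild-type trajectory to stay inside the 0.90–0.95
  per-round band that such campaigns show; the spread makes the best of
  ~5000 variants roughly 10–20× fitter than the wild type, which under the
  default selection strengths enriches them a few-fold per late round —
  the regime in which rare-variant selection is actually difficult.
* **Selection.** Each round reweights the pool deterministically,
  f′(s) ∝ f(s)·w(s)^β, with β = 0.10, 0.15, 0.20, 0.25, 0.30 over the five
  sequenced rounds (rising β models increasingly stringent washes). The
  reweighted pool is then resampled through a multinomial *capture
  bottleneck* of 10⁵ cells — a sorting round retains only ~0.1–2.5% of the
  ~10⁷ cells sorted — so rare clones can go extinct and round-to-round
  trajectories carry genuine demographic noise. Both sequencing replicates
  observe the same post-bottleneck culture, as in a real campaign where
  the duplicate is at the sequencing step, not the sort. `bottleneck=None`
  recovers the pure deterministic update (used by the closed-form
  invariant test: Δlog f = β·log w − log Z).
* **Sequencing.** Each replicate is an independent multinomial draw of D
  reads (default 10⁶) from the pool. Reads can be emitted as FASTQ using a
  30-residue synthetic amplicon (anchor + scaffold + the ten mutated
  sites as two five-residue blocks, one fixed codon per residue) with
  per-sample frame offsets and an optional per-base substitution error
  rate to stress the QC filter.

Everything derives from one integer seed; identical seed and config give
bit-identical output.

### What the generator does and does not emulate

It reproduces the features the analysis is sensitive to: wild-type
dominance, the rare-variant tail, replicate structure, finite depth,
demographic bottlenecks, and monotone selection on a latent fitness. It
does **not** model bead-capture physics, off-rate-dependent wash survival,
PCR amplification bias, position-dependent sequencing error, epistasis
(fitness is strictly additive), or the negative sort against disaggregated
antigen (conformational specificity is not encoded in a single scalar
fitness). Passing benchmarks therefore show the pipeline ranks clones
correctly when enrichment reflects additive latent fitness through noisy
sampling — not that any real campaign satisfies those assumptions.

## Benchmark protocol

`run_benchmark` mirrors the full analysis on one simulated campaign:
matrices from the permissive replicate-common set; scoring restricted to
clones common to both replicates of every early round; PSERMs for the last
two round transitions; top-40 overlap; cysteine filter. Recovery metrics:
Spearman correlation of each ranking with true log-fitness; the fraction
of the true top-1% variants captured in each metric's top 40; and the mean
true fitness of the final selection against the library's 90th fitness
percentile. The acceptance script aggregates ten campaigns with seeds
derived from `--seed`.

## Numerical and interface choices

* Deterministic outputs everywhere: clone tables sort by descending
  terminal-round frequency then lexicographically; rankings break ties
  lexicographically; re-running the pipeline on identical inputs is
  byte-identical (the run manifest records config hash and input
  checksums).
* PPM columns sum to 1 within 1e-9; the matrix chain agrees with
  brute-force loop references to 1e-12 (tested on thousands of random
  instances).
* Degenerate inputs: an empty round yields a valid all-zero count matrix
  but refuses PPM construction (the √N pseudocount degenerates at N = 0);
  a single-clone round is fine — every other cell holds pseudocount mass.
* Round labels are opaque ordered strings; sorted-but-unsequenced rounds
  simply never appear, and nothing assumes contiguous numbering. PSERM
  pairs must be consecutive entries of the configured round order.
* Replicate count is configurable with a minimum of two; the default
  workflow assumes duplicate sequencing.
* Problem sizes in the shipped tests and the acceptance script (10⁵-read
  FASTQ round trips, ten benchmark campaigns at 10⁶ reads) were chosen to
  exercise realistic depths while keeping a full run in the order of
  seconds to a few minutes on one CPU.

## Known limitations

* The pseudocount and "total sequences observed" interpretations follow
  the literal construction above; codebases differing in those details
  will produce slightly shifted (but near-identically ranked) scores.
* Enrichment-ratio metrics are undefined for clones absent from a
  reference round; comparisons between metrics are therefore over the
  clones each metric can rank, as in practice.
* The additive landscape cannot express epistasis, so the benchmark is
  silent about PSERM behaviour on strongly epistatic campaigns.
* Net-charge values are side-chain Henderson–Hasselbalch sums; they ignore
  charge–charge interactions, local environment shifts and bound ions.
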