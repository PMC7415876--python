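# Methods

## The advising model

A parameter advisor has two parts: an **advisor set** — an ordered list of
parameter vectors, one value per tunable parameter of the assembler — and an
**estimator** that ranks candidate assemblies. Advising a sample means
producing one assembly per vector in the set and returning the assembly the
estimator scores highest. The invocations are independent, so the contract
is purely a deterministic reduction: the argmax over scaled AUC, ties broken
by the earliest position in the set. Placing the default vector first
therefore guarantees structurally that advising never returns an assembly
scoring below the default's.

## The estimator

### Matching

A predicted transcript is compared with the reference catalogue by its
splice structure, not its exact exon ends:

- **multi-exon** predictions match iff some reference transcript on the same
  chromosome and a compatible strand has an identical intron chain (the
  ordered list of intron intervals). Transcripts with unknown strand (`.`)
  are compatible with either strand.
- **single-exon** predictions have no introns; they match a single-exon
  reference transcript on the same chromosome/compatible strand when the
  reciprocal overlap — overlap length divided by the longer transcript's
  exonic length — is at least `single_exon_overlap` (default 0.8). The
  threshold is configurable because single-exon equivalence is inherently
  fuzzy; 0.8 is strict enough that the synthetic decoy construction (below)
  can guarantee non-matches.
- ties (several reference transcripts with the same chain) resolve to the
  lexicographically smallest reference id, for reproducibility.
- predictions on chromosomes absent from the reference are unmatched, not
  errors.

Identical predicted intron chains are *not* deduplicated before scoring:
each kept prediction counts toward precision, while a reference transcript
counts only once toward sensitivity however many predictions hit it.

### Threshold sweep and area

Each predicted transcript carries a coverage value (the assembler's
abundance estimate, read from the `cov` attribute by default, falling back
to `coverage` then `FPKM`; absent coverage counts as 0). Thresholds are the
distinct coverage values in decreasing order; at threshold *t* the kept set
is every prediction with coverage ≥ *t*, giving one
(sensitivity, precision) point. The estimator is

    auc_scaled = 1e4 × ∫ precision d(sensitivity)

by the trapezoid rule over the points, prepended with an anchor at
(0, precision of the highest-threshold point) and with no extrapolation
beyond the lowest threshold. Duplicate sensitivity values contribute
zero-width segments. Consequences used as test invariants: the value lies in
[0, 1e4], is bounded by 1e4 × max sensitivity, reaches 1e4 exactly for a
perfect assembly, never decreases when a new top-coverage true positive is
added, and never increases when a bottom-coverage false positive is added.
An optional `bins` parameter replaces the distinct-value thresholds with a
fixed number of evenly spaced cutoffs, for cross-checking against external
fixed-binning scorers; the default sweep is exact and is what every test and
experiment here uses.

## Coordinate ascent

The advisor set is learned per training sample by greedy coordinate ascent
from the assembler's default vector. Coordinates cycle in declaration
order; a coordinate's proposals are its single-step moves — ±step for
numeric parameters (clamped to bounds; × / ÷ step when the parameter is
marked multiplicative), the flip for booleans, every alternative for
categoricals. Under the default best-of-both policy all proposals for the
coordinate are evaluated and the best is accepted iff it exceeds the
incumbent by strictly more than `min_improvement` (default 0 — equal-AUC
proposals are rejected, which guarantees termination). A full pass with no
acceptance stops the search; `max_passes` (default 20) is a safety bound.
The objective is memoized, so no vector is ever evaluated twice; a failed
assembler run scores 0 with a warning (except on the start vector, where it
is an error). A single deterministic start with no restarts is a deliberate
choice: assembler AUC landscapes empirically have very few local maxima, so
greedy ascent recovers (near-)optimal vectors at a predictable budget of
objective calls. Line searches and simultaneous multi-coordinate steps are
intentionally absent.

The per-sample optima, deduplicated and tagged with their source sample,
form the advisor set; the default vector is prepended unless the caller
opts out.

## Subset selection

For resource-limited advising the training signal is an examples × vectors
matrix of scaled AUC values. A subset's advising score is the mean over
examples of its best column — exactly the training advising AUC. Greedy
forward selection produces nested subsets for k = 1..k_max, each step adding
the vector with the largest marginal gain (ties: lowest index, so exhausted
gains fill remaining slots in index order). An exhaustive mode enumerates
all C(n, k) subsets (refusing beyond a budget) and doubles as the oracle in
tests; greedy provably coincides with it at k = 1 and, empirically on
dominant-column matrices, at larger k.

## The mock assembler

Testing the advising loop against real Scallop/StringTie runs needs BAM
files and hours of compute, so the package ships a mock assembler that
preserves the *shape* of the problem. A mock sample is a YAML landscape
declaring a planted optimum vector p\*, per-parameter weights w, and a
reference transcriptome. Assembly quality is separable and unimodal:

    quality(p) = exp(−Σᵢ wᵢ dᵢ(p, p*)²),

with dᵢ the per-parameter distance in units of the spec's step (0/1 for
booleans and categoricals); quality(p\*) = 1. A bimodal variant (second
optimum scaled by `mode2_height`) exists for robustness experiments. The
emitted assembly contains `round(quality · max_sensitivity · |reference|)`
true positives — reference transcripts copied verbatim, selected
highest-priority-first under a seed-derived fixed priority, with log-normal
high-mean coverages — plus `round(fp_max · (1 − quality))` decoys with
low-mean coverages. Priorities, coverages and the decoy pool depend only on
the landscape and sample seeds, never on the vector, so the TP sets of two
vectors are nested and AUC is monotone in quality; the maximum achievable
AUC is 1e4 × max_sensitivity, attained exactly at p\*.

Decoys are built by moving one intron boundary of a multi-exon reference
transcript inward by at least 2 bases and checking the perturbed chain
against every reference chain, so a decoy can never accidentally match and
planted labels are exact ground truth. Decoys keep their source gene's
locus, mimicking plausible mis-assemblies rather than random genomic noise.

### Study conditions

The desk-scale experiments (acceptance script and end-to-end tests) fix:
a 450-gene synthetic reference (~900 transcripts on 3 chromosomes, exons
80–400 bp, introns 60–2000 bp, ~10% single-exon transcripts), a 4-parameter
space (two integers, one real, one boolean), `max_sensitivity` 0.5,
`fp_max` 100, TP coverages log-normal(ln 20, 0.5) vs FP log-normal(ln 2,
0.5), 10 samples, and 5 random comparison sets. Planted optima sit within
±2 steps of the default per numeric coordinate with weights in [0.1, 0.3].
That placement is a granularity condition, not a convenience: the mock's TP
count is an integer, so if the quality at the default were vanishingly small
(optima far away, steep weights), entire neighbourhoods would round to the
same assembly and greedy ascent — correctly — could not move. With these
settings every single-coordinate step toward the optimum changes the TP
count, so optimum recovery genuinely tests the search rather than the
rounding.

### What the mock does and does not show

Passing tests on the mock demonstrate the estimator, the search, the
argmax machinery and the selection logic — not that advising improves real
assemblies. Real parameter landscapes are only empirically close to
unimodal, real coverage distributions are not log-normal, real references
are ~200,000 transcripts (hence real sensitivities and AUCs are far
smaller), and real assembler failures are messier than a clean nonzero
exit. The Scallop/StringTie adapters carry exactly that external contract
(value-style vs presence-style boolean flags, `-i`/positional BAM
argument, output-file check) and are exercised only through their rendering
logic in the default test suite.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere (GTF convention); no
  half-open conversions in the public model.
- GTF writing emits one `transcript` row plus `exon` rows with `gene_id`,
  `transcript_id` and (when present) `cov`, coverage serialized with
  `repr()` so read∘write round-trips are exact.
- Non-numeric coverage attributes parse as absent with a warning — hard
  failures on third-party GTF dialects would be worse.
- Advisor-set files are TSV with a provenance column; reading validates
  every row against the parameter space and rejects duplicates.
- All generators (reference, assembly, landscape, random sets) are pure
  functions of their seed; CLI runs write a JSON manifest (options, input
  digests, seeds, version) sufficient to reproduce outputs bit-for-bit.
- Ties everywhere (advising argmax, greedy selection, matching) break by
  position/index or lexicographic order — never by hash order or RNG state.
- The shipped Scallop (18-parameter) and StringTie (9-parameter) space
  files transcribe names, defaults and flags from each tool's public
  documentation; the bounds and step sizes are this package's choices and
  each file records its source. Verify flags against your installed release.

## Known limitations

- Matching implements only the exact intron-chain / reciprocal-overlap
  equivalence class, not the full taxonomy of partial-match codes used by
  annotation-comparison tools, and no nucleotide- or exon-level metrics.
- The advisor runs assembler invocations serially; the contract permits
  parallel execution but no executor is built in.
- Coordinate ascent takes single steps on one coordinate at a time; strongly
  correlated parameters would slow it (though they did not arise here).
- De novo (reference-free) estimators are out of scope; the estimator is
  bounded by the completeness of the reference, and penalizes genuinely
  novel transcripts by construction.
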