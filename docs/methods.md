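# Methods

This note documents the models, algorithms and numerical choices behind
crisprforge, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Sequence model and distances

All sequences are uppercase strings over `{A, C, G, T, N}`.  `N` matches
nothing — not even another `N` — in both Hamming and edit-distance
computations.  This is deliberately conservative: an ambiguous base should
never help a window clear a mismatch budget.  Edit distance is unit-cost
Levenshtein, computed by a numpy-vectorised rolling-row dynamic program
(repeats and spacers are under ~80 bp, so the quadratic cost is
irrelevant); the test suite cross-checks it against an independent
implementation (edlib) on thousands of random pairs.

Because array orientation is generally unknowable without cas-gene
context, strand-insensitive comparisons use the **oriented distance**
`min(lev(a, b), lev(a, revcomp(b)))`, and spacer uniqueness uses the
**canonical orientation** (lexicographic minimum of a sequence and its
reverse complement).

## De novo detection

The detector follows the classic seed-and-check recipe for CRISPR finding:

1. **Seed chains.** Every exact 8-mer whose occurrences recur with
   consecutive gaps in `[min_repeat + min_spacer, max_repeat + max_spacer]`
   (defaults `[37, 120]`) and at least `min_copies` (default 3) occurrences
   forms a candidate chain.
2. **Boundary extension.** Repeat boundaries grow outward from the seed by
   per-column voting across copies.  A column passes only if the majority
   fraction clears `column_agreement` (default 0.75) **and** the number of
   dissenting copies is at most `voters // 6` (unanimity below six copies).
   The fraction threshold alone is not enough: with 4–6 copies a random
   spacer column reaches 75% agreement 6–20% of the time, which would
   routinely overshoot the boundary by a base.  Up to two consecutive
   failing columns (e.g. a position mutated in two copies) are *bridged*,
   but committed only once two consecutive passing columns follow, so a
   single chance-conserved spacer column cannot drag flanking junk into
   the repeat.  A final trim removes terminal failing columns.
3. **Consensus rescan.** The refined consensus is scanned back over the
   contig at ≤ 3 mismatches and hits are re-chained by spacer-sized gaps.
   This recovers copies whose seed k-mer was mutated, separates multiple
   arrays sharing one repeat, and — because boundaries are re-extended with
   the full copy set — makes the boundary vote considerably less noisy
   than the seed-chain vote.  On simulated arrays with per-copy
   substitution rate 0.02 the detector places both boundaries within 1 bp
   of truth in ≈ 98% of arrays (the residual errors are 2-bp undershoots
   where two adjacent terminal columns each carry a mutation).
4. **Validation.** An array is accepted if it has ≥ `min_copies` complete
   copies, consensus length in `[19, 48]`, every spacer length in
   `[18, 72]`, max/min spacer length ≤ 2.5, no spacer pair at ≥ 80%
   identity, and no spacer at ≥ 80% identity to the repeat (identity =
   1 − lev/longer length, same strand).  Rejections carry enumerated
   reasons.
5. **Truncated ends.** Contigs frequently cut arrays mid-repeat.  If less
   than (max spacer + repeat length) of sequence precedes the first (or
   follows the last) repeat, a boundary fragment of length `t ≥ 5`
   matching the corresponding consensus end within `ceil(3 t / L)`
   mismatches is attached as a truncated copy, provided a spacer-sized gap
   separates it from the complete array.  Among admissible fragments the
   score `t − 3·mm` is maximised: the consensus end can be locally
   self-similar, in which case a longer-but-inexact placement could
   otherwise sneak under the prorated budget.
6. **Overlap resolution.** Overlapping accepted candidates keep the one
   with more copies, then longer span, then leftmost.  Output is
   deterministic; GFF3 emission (1-based inclusive) is byte-stable.

## Similarity search and novelty

Scanning a query repeat against a target evaluates *every* window on both
strands by Hamming distance (`N` mismatches everything) — the
implementation is a vectorised brute-force scan, so its contract is
exactly the sliding-window semantics the tests' independent oracles
implement.  Same-strand hits whose starts lie within half a query length
collapse to the lowest-mismatch (tie: leftmost) hit.  Gapless matching is
a deliberate choice: at repeat lengths of 24–48 bp with small mismatch
budgets, alignments with indels are not meaningfully distinct.

Hits chain into arrays when consecutive same-strand gaps are spacer-sized;
**two** chained copies suffice here (the query supplies the prior that the
repeat is real).  A repeat is **novel** against a reference collection if
no reference contains a chained array of it within 4 mismatches — a lone
repeat occurrence is not an instance, since isolated hits arise easily by
chance and carry no array structure.

## Targeted assembly

Recruitment keeps reads containing the *entire* query repeat within 3
mismatches on either strand (equivalent to a brute-force scan; verified
against one).  Reads shorter than the query are skipped and counted.
Read qualities are carried through I/O but ignored by recruitment and
assembly.

The assembler is a small node-centric de Bruijn graph over canonical
(strand-merged) k-mers — recruitment captures both strands, so strands
must be merged.  Defaults: `k = 45`, chosen to exceed the repeat length so
that repeat+partial-spacer k-mers are unique and the array path is linear;
`min_count = 2` drops singleton k-mers as presumptive sequencing errors
(use 1 for very low coverage).  Contigs are maximal non-branching paths;
one round of tip clipping removes unitigs shorter than 2k that dead-end on
exactly one side.  Contigs are reported in canonical orientation, ordered
by length then sequence, and re-oriented so the query repeat reads forward;
contigs without any repeat hit are suppressed and counted, since they
cannot be CRISPR loci of the query.  Assembly is deterministic for a fixed
read set and parameters.

On error-free simulations (6 genomes of 20 kb, 10 planted arrays, 100-bp
reads at 50×) every emitted CRISPR contig is an exact substring of its
source genome and every planted spacer inventory is recovered in full;
these problem sizes are the package's standing validation configuration.

## Catalog and spacer analytics

* **Selection filter** (inclusive bounds): repeat length 24–40, ≥ 4
  complete copies (truncated copies do not count), average mismatch of
  complete copies vs the consensus ≤ 1.0.
* **Clustering** is greedy and CD-HIT-like: sequences sorted by (length
  desc, sequence asc); each joins the first representative within the
  identity threshold, where identity = 1 − oriented distance / longer
  length.  The identity denominator is always the longer sequence — a
  documented divergence from CD-HIT's short-sequence convention, chosen
  for symmetry and testability.  Because the greedy pass is already
  orientation-aware, the final reverse-complement-pair dedup (drop the
  cluster with the lexicographically larger representative) is usually a
  no-op, but it is retained for inputs pre-expanded with reverse
  complements.
* **Repeat network**: edges at oriented distance ≤ 10 (threshold
  inclusive, configurable), exported as TSV and GraphML.
* **Body-site classes**: a repeat seen in fewer than 5 samples is "rare";
  otherwise it is assigned every site covering more than 10% of that
  site's samples (multi-site classes join names with `+`), else
  "unassigned".
* **Spacer sharing**: binary cluster × sample incidence; pairwise shared
  counts are tagged by relationship tier (same subject+site resample /
  same subject cross-site / cross-subject) and summarised by tier means.
* **Proto-spacers**: gapless full-spacer placements at ≥ 90% identity,
  ≥ 30 bp; the inclusive identity threshold is guarded with a small
  epsilon against float representation (`(1−0.9)·30` evaluates just below
  3).  Flanks (default 10 bp) are reported in proto-spacer orientation,
  clipped at genome ends and padded with `N`.
* **PAM profile**: per-position base frequencies over the flanks (N mass
  excluded and reported) and, per flank, the dinucleotide of the single
  most conserved adjacent position pair with its frequency.  The
  per-position-pair definition is what makes a planted PAM report
  frequency 1.0 while uniform flanks stay below 0.2; summing a
  dinucleotide's frequency across positions would satisfy neither.

## Synthetic data: what it emulates, and what it does not

The generator plants CRISPR loci (repeat copies with optional per-copy
substitutions; spacers i.i.d. uniform, re-drawn until every pair *and*
every spacer-vs-repeat identity stays below 0.8, so planted loci always
satisfy the detector's uniqueness checks) into i.i.d. uniform backgrounds;
simulates uniform-coverage single-end reads from both strands with
substitution-only errors; builds multi-sample communities whose spacer
inventories share configured fractions between same-site resamples (f1),
same-subject cross-site pairs (f2) and cross-subject pairs (f3), with
f1 > f2 > f3 enforced; and embeds (optionally mutated) proto-spacers with
a PAM immediately downstream into mock phage genomes, on either strand.
Everything is deterministic under a seed.

Passing tests on these fixtures demonstrates algorithmic correctness —
exact recovery, oracle equivalence, tier ordering — but not robustness to
properties real data have and the generator lacks: indel sequencing
errors (the matchers are gapless by design), GC bias and non-uniform
coverage, strain mixtures with diverged repeat variants, chimeric reads,
and quality-correlated errors.  Default simulation scales (6 × 20 kb
genomes at 50×; 24-sample communities with 20-spacer inventories) are the
package's chosen validation sizes, small enough to run routinely.

## Known limitations

* Single-end semantics only; mates of recruited reads are not pulled in.
* No cas-gene detection, so array orientation is by convention, not
  biology.
* Proto-spacer alignment is gapless; a gapped (BLAST-like) mode would
  recover marginally diverged proto-spacers that the current scan misses.
* The novelty test's "instance = chained array" rule is a declared
  interpretation; callers wanting single-hit sensitivity can scan
  references directly.
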