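# Methods

This note documents the models and procedures implemented in dbgasm, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Graph representation

Nodes are canonical k-mers (lexicographic minimum of a k-mer and its
reverse complement); an edge is a canonical (k+1)-mer whose prefix and
suffix k-mers are its endpoints.  This makes strand symmetry structural:
assembling the reverse complement of the input yields the identical
canonical unitig set.  k is required to be odd so no k-mer equals its own
reverse complement.  (k+1)-mers *can* be palindromic; a unitig walk
therefore stops whenever it would revisit a canonical node, which
fragments such paths conservatively instead of over-spelling them.  At odd
k on random sequence this is vanishingly rare.

Storage is plain Python dictionaries keyed by strings.  The contract is
determinism and strand canonicalization; bit-packing is an implementation
freedom deliberately not taken at desk scale.

## Sparse graph

Along unbranched stretches only every g-th k-mer is stored as an anchor;
the ≤ g−1 bases to the next anchor are kept as an extension string, and
anchors are forced at every branching or merging node.  The sparse store
is computed as a compaction of the full adjacency, so the spelled unitig
multiset is identical to the dense graph's at equal k for every input and
every g — that equivalence, not memory engineering for 100+ GB datasets,
is the contract here, and it is what the test suite checks (the default
skip factor g=4 compresses the anchor count by ~4x).  The shorter-k
behaviour reported for streaming sparse builders is reproduced by
parameter choice, not algorithmic divergence.

## Error correction

The count-of-counts histogram of a spectrum at adequate coverage is
bimodal: an error peak at count 1 and a coverage peak near the mean k-mer
depth.  `auto` places the trusted cutoff at the first local minimum
between the two (falling back to 2 with a warning if no valley exists,
e.g. on error-free data).  A k-mer is trusted when its canonical count
reaches the cutoff.

FAST mode scans windows left to right; at the first untrusted window it
tries the three alternative bases at each position covered only by
untrusted windows — starting from the last base of the first untrusted
window, where an isolated error must sit — and accepts a substitution only
if it is unique and makes every window covering the position trusted, up
to `max_edits` (default 2) times.  DEEP mode is a bounded depth-first
search over joint substitutions (branch budget default 64), scoring
complete candidates by (number of untrusted windows remaining, then total
spectrum count of all windows); a tie between distinct best candidates is
reported as ambiguous and the read left unchanged.  Correction is
substitution-only — read length never changes — matching the Illumina
error profile the pipeline targets.  Uncorrectable reads are kept by
default (`--drop-uncorrectable` discards them).

A spaced k-mer spectrum (two blocks of ⌈k/2⌉ matched positions separated
by a skip, default 4) can be supplied as a corroboration filter: a
candidate edit must then also make the spaced k-mers covering the site
trusted.  The precise consecutive/spaced combination rule and the exact
seed shape are design choices of this package, exposed as parameters, and
off by default.

## Multi-k contig assembly

Round 1 builds and cleans the graph at k_min.  Each later round (k
increasing by an even step, default 8) builds the k'-graph from all reads
plus the previous round's unitigs injected as pseudo-reads whose edges are
protected from every cleaning operation, so assembled sequence can never
be lost when per-k' edge multiplicity drops below the cleaning thresholds.
Reads are mapped back to the previous unitigs (full-length ungapped, ≤ 2
mismatches); unplaced reads are still k-merized but their private edges
face the low-coverage filter.  Edge multiplicities are recomputed from
reads each round rather than carried over.  The final contigs' depth is
recomputed by read mapping.  Any exact repeat with copy length L,
k_min−1 ≤ L < k_max−1 and unique flanks is resolved on error-free data.

Cleaning defaults: tip length 2k bp, bubble divergence 0.03 (edit distance
over the longer arm, computed with edlib), coverage cutoff 1.  Bubble
merging folds the lower-coverage arm into the higher-coverage one, adding
its mean multiplicity; coverage ties keep the arm whose canonical spelling
is smaller — determinism is preferred over faithfulness to unspecified
historical behaviour throughout.

## Scaffolding

A mate pair placed on two contigs yields a link with
`gap = insert − d_a − d_b`, where d is the distance from a read's
outermost base to the linked contig end; mate-pair (RF) libraries are
flipped to the innie frame at link creation so downstream logic is
library-agnostic.  Links are bundled per contig pair and orientation
**within one library rank**; gap observations beyond 3 library sd of the
bundle median are trimmed.  Two estimator details matter at contig sizes
comparable to the insert:

* mixing insert sizes in one bundle length-biases the gap (large inserts
  preferentially reach farther contigs), hence per-rank bundling;
* a pair can only span a gap if its insert exceeds gap + both read
  lengths, biasing observed gaps high by ≈ sd²/(μ − gap − read span); the
  pipeline adds this correction back (one fixed-point step, skipped when
  the denominator is within one sd of zero).

The bundle's `gap_sd` is the standard error sd/√support.

Contig depth is recomputed from full-length read placements, normalizing
by the effective length len − read_len + 1 rather than the raw length —
otherwise placement edge effects halve the apparent depth of contigs only
a couple of read lengths long, which are exactly the short repeat copies
whose depth matters.  Contigs above 1.5x the modal depth are treated as
multi-copy repeats and kept out of linearization: their bundles point at
several loci at once, blocking their own joins and, via transitive
reduction, deleting the valid flank-to-flank bundles around them.  They
remain in the output as singleton scaffolds, and gap closing reconstructs
the repeat copy inside the joined gap.

Heterozygous pairs: contigs at 0.3–0.7 of the length-weighted modal depth
(over contigs ≥ 1 kb), lengths within 2x, and locally equivalent in the
link graph — sharing flank neighbors on both sides, or on one side plus a
direct cross-link between the two (reads without a distinguishing variant
all map to one allele, so the weaker allele can lose one flank bundle).
The higher-depth member is kept; the other is masked from scaffolding but
still emitted.  Depth ties keep the smaller id.

Ranks are processed small-insert first; each rank lifts its bundles onto
the current super-contigs, removes transitively redundant edges (an A–C
edge whose gap matches gap(A–B)+len(B)+gap(B–C) within 3 pooled sd, pooled
sd = √(sd₁²+sd₂²)), and joins only ends with exactly one surviving
candidate; cycles break at the weakest join.  After every rank beyond the
first, existing junctions are re-examined with the current rank's bundles:
a junction that no pair spans consistently, while one side has ≥
min_support (default 3) links to contigs outside the scaffold, is cut —
re-running rectification after each rank rather than once at the end.
Junctions with any consistent spanning pair are never cut.  After all
ranks, weak candidates (support < min_support) are re-admitted where a
path of accepted bundles through a third contig implies the same layout
within 3 pooled sd, or where they are the unique, unconflicted link
between two dead ends; such joins are tagged `recovered`.

Gaps keep their signed estimates; rendered FASTA shows max(gap, 1) N's.
Negative estimates (overlapping ends) are left for gap closing.

## Gap closing

Each internal gap gets flanks of 2·(max library sd) + read length bases.
A read is recruited when its placed mate implies it lies in the gap
(mate position ± insert ± 3 sd) and the read itself is unplaced or placed
only with mismatches.  Extension grows one base at a time from both flanks
inward: reads anchor by an exact k_fill-mer (default 25) match to the
consensus tail, vote with weight 1 (halved if their anchored overlap
carries mismatches, dropped beyond 2), and the column is fixed only when
the runner-up weight is below 0.8 of the winner — otherwise extension
stops at the ambiguous column, which is what prevents wrong-copy fills
inside diverged repeats.  Reads recruited in earlier cycles keep voting in
later cycles; the cycle-local alternative is kept behind
`legacy_cycle_local` for comparison, and the cumulative rule dominates it
on cross-cycle conflict fixtures by construction.  Pairs with both mates
unplaced are re-tested against the grown extensions each cycle and join
with the next cycle's stamp.

A gap closes when the two extensions overlap ≥ k_fill bases with ≤ 1
mismatch; negative estimates are first checked for a direct flank overlap,
and a negative closure is rendered by trimming the duplicated overlap.
Fills are capped at est_gap + 3 sd + 2 read lengths (`partial` beyond
that).  Flanks are byte-stable and the assembly's total N count is
non-increasing across cycles.

## Simulator

Genomes are i.i.d. with a GC parameter; repeat families are generated once
and pasted at uniform non-overlapping positions; diploid genomes add a
second haplotype with i.i.d. substitutions (optionally confined to a
region).  Fragments are Normal(avg_ins, sd) truncated to
[2·read_len, 2·avg_ins]; pair count = round(coverage·L/(2·read_len)); FR
orientation unless the library is RF; errors are i.i.d. substitutions.
The first four fragments of each library are pinned, two per end of the
sequence, so terminal (k+1)-mers reach multiplicity ≥ 2 and byte-exact
reconstruction is a well-posed target; all remaining fragment starts are
uniform.  Every read carries full provenance (haplotype, position, strand,
planted errors).

What the simulations do not emulate: indels, quality-dependent or
GC-biased error profiles, coverage bias, PCR duplicates, chimeric
fragments.  Passing tests therefore demonstrate algorithmic correctness
under the substitution-only model at desk scale (5–100 kb genomes), not
performance on real libraries or large genomes.

## Evaluation

N50 is the largest L with sequences ≥ L summing to half the assembly
(NG50: half the given genome size, absent when unreachable).  Reference
coverage and structural errors come from seeded exact-match chaining
(31-mer seeds, maximal ungapped extension, blocks ≥ 100 bp): coverage is
the fraction of reference positions in any block, and each junction
between consecutive blocks that flips strand or jumps more than 2x the
maximum insert counts one structural error.  This operational definition
is self-contained rather than delegating to an external evaluation
pipeline; it under-counts errors that a gapped aligner would resolve into
multiple blocks, which is acceptable at toy scale.

## Problem sizes

The test suite and acceptance script use 5–100 kb genomes at 12–40x
coverage — sizes at which every stage, including the pure-Python k-mer
counting, completes in seconds to a few minutes while still exhibiting the
phenomena of interest (repeat fragmentation, het bubbles, chimeric joins,
cross-cycle gap conflicts).
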