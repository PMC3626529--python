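# dbgasm

A desk-scale de novo short-read genome assembler, built so that every stage
of a modern de Bruijn graph assembly pipeline is small enough to read and
verifiable against truth-known simulations.  It is aimed at people studying
or teaching assembly algorithms — each stage is an ordinary Python module
with a contract and a test, not a black box.

The pipeline mirrors the classic six-module architecture of short-read
assemblers of the SOAPdenovo family:

1. **Error correction** — canonical k-mer counting, a trusted/untrusted
   cutoff at the first valley of the count histogram, then substitution
   search: a greedy FAST pass and a bounded depth-first DEEP pass that
   scores joint edits by remaining untrusted windows.  A spaced (gapped)
   k-mer spectrum can corroborate candidate edits.
2. **Graph construction** — nodes are canonical k-mers, edges canonical
   (k+1)-mers, so the graph is strand-symmetric by construction.  A sparse
   mode stores only every g-th k-mer along unbranched stretches (anchor +
   extension string) and spells exactly the same unitigs.
3. **Contig assembly** — tip clipping, bubble popping (edlib edit distance),
   low-coverage edge removal, unitig extraction; and an iterative multi-k
   mode: assemble at small k, then rebuild at larger k from reads threaded
   against the previous contigs plus the contigs themselves as protected
   pseudo-reads, resolving repeats with k_min−1 ≤ length < k_max−1.
4. **Read mapping** — seeded, full-length, ungapped best placement of each
   read on the contig set.
5. **Scaffolding** — mate-pair links with gap = insert − d_a − d_b, bundled
   per library rank with outlier trimming and a selection-bias correction;
   heterozygous contig pairs (half depth, shared flank neighbors) masked,
   keeping the higher-depth allele; rank-by-rank linearization with
   transitive reduction; chimeric junctions cut when a larger-insert
   library never spans them; weakly supported links recovered when the
   surrounding topology independently implies them.
6. **Gap closing** — per-gap local assembly growing a consensus inward from
   both flanks, where reads recruited in earlier cycles keep voting in
   later cycles (cumulative evidence), closing when the two extensions
   overlap by ≥ k_fill bases.

A seedable simulator (genomes with planted repeats, diploid divergence
regions, multi-library paired-end reads with substitution errors and full
per-read truth) and an evaluator (N50/NG50, reference coverage and
structural errors by seeded exact-match chaining) complete the toolkit.

## Worked example

```bash
dbgasm simulate --length 20000 --coverage 30 --insert 500,20,1 \
    --seed 5 --out-prefix sim
dbgasm all --config sim.config --kmer 31 --skip-correct --out-prefix asm
dbgasm evaluate --assembly asm.scaffolds.fa --reference sim.genome.fa \
    --out-prefix ev
```

prints

```
simulated 20000 bp genome, 1 library -> sim.*
1 contigs; 1 scaffolds (N50 20000 bp); 0/0 gaps closed
{"n_seqs": 1, "total_len": 20000, "n50": 20000, "ng50": 20000,
 "largest": 20000, "reference_coverage": 1.0, "structural_errors": 0}
```

i.e. the 30x error-free library reassembles the 20 kb simulated genome into
a single contig identical to the reference: N50 equals the genome length,
reference coverage is 1.0 and no junction in the assembly maps to
non-collinear reference loci.  With `--error-rate 0.005` the same pipeline
first corrects reads against the k-mer spectrum (`dbgasm correct` reports
the chosen cutoff and per-status counts); with a repeat planted
(`--repeat 35,2`) a single k fragments the assembly and
`--kmer-range 21,51,10` restores a single contig.

The library config is the classic key=value dialect
(`max_rd_len`, `[LIB]`, `avg_ins`, `reverse_seq`, `asm_flags`, `rank`,
`q1`/`q2`), so existing configuration packages work as-is.

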