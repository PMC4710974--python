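# Methods

This note documents the models and rules `txpipe` implements, the defaults
it ships, and what its synthetic tests do and do not demonstrate.

## Data model and coordinates

All coordinates are GTF-native: 1-based, inclusive at both ends.  A
transcript is an ordered, non-overlapping exon chain on one strand of one
chromosome; consecutive exons must be separated by an intron of length ≥ 1.
A transcript's *intron chain* — its ordered (donor, acceptor) pairs, where
the donor is the last exonic base before a gap and the acceptor the first
after it — identifies a splice structure independently of transcription
start/end, and is the unit of identity for merging and for the `equal`
class code.  GTF attribute strings are preserved verbatim so a
read→write cycle is lossless; on output, records are ordered by
(chrom, start, transcript_id) and attributes by
(gene_id, transcript_id, then alphabetical), which makes outputs
byte-deterministic and diff-able.

## Cross-sample merging

Multi-exon transcripts from different samples collapse when their intron
chains are identical; the representative takes the union of terminal-exon
extents, so differing transcription start/end calls do not fragment a
locus.  Single-exon transcripts collapse when their exons overlap on the
same strand (≥ 1 bp by default; a minimum-overlap fraction of the shorter
exon is configurable), and an overlap cluster is replaced by its spanning
interval.  Merged transcripts then cluster into loci by same-strand span
overlap.  Every merged transcript records which samples contributed it;
ids are assigned in genomic order, so the result is invariant to sample
ordering.

## Classification against the reference

Five class codes, in strict precedence:

1. `equal` — intron chain identical to a reference transcript.  For
   single-exon transcripts (empty chain) exonic overlap with the matched
   single-exon reference transcript is additionally required; an empty
   chain alone would match any single-exon gene genome-wide.
2. `novel_isoform` — shares ≥ 1 intron with a same-strand reference
   transcript, or overlaps a same-strand reference gene's exons.  The
   second clause covers contained fragments and exon-overlapping variants,
   which a finer class alphabet would label separately; for the downstream
   decision (annotated vs novel) they behave identically.
3. `intronic` — all exons inside a single intron of a same-strand
   reference transcript (pre-mRNA and intronic-noise signature).
4. `antisense` — exonic overlap with reference genes on the opposite
   strand only.
5. `intergenic` — no exonic overlap with any reference gene.

Reference exons are indexed in per-chromosome interval trees; a brute-force
all-pairs oracle in the test suite checks the indexed path on random
instances.

## Filtering

*Single-exon rule.*  Any transcript containing a splice junction is kept:
a junction is strong evidence of a processed transcript.  A single-exon
transcript is kept only when present in a **strict** majority of samples
(> majority_fraction × n, default 0.5, so exactly half fails and is
reported as a tie).  Single-exon transcripts classified `intronic` are
removed regardless of presence.  Presence is counted over all samples; a
per-group variant is deliberately not given default semantics.

*Coverage rule.*  A locus enters DE testing only if its total read count
across samples is ≥ `min_locus_reads` (default 10) and its best per-sample
FPKM is ≥ `min_fpkm` (default 0, i.e. disabled).  The read floor is a
pragmatic default for "too low to test"; it is configurable and every
removal is written to the filter report with its reason.

Both filters are subset operations and idempotent, and never remove a
multi-exon transcript — properties the suite asserts on random inputs.

## Coding potential

A novel locus is a *coding candidate* when **any** isoform carries a
significant ORF: one coding isoform disqualifies the whole locus from
being called noncoding.  An ORF is an ATG…stop codon run on one of the
three sense-strand frames of the spliced sequence; length is counted in
codons excluding the stop, the significance floor is 100 codons, and
codons containing N break the run (conservative: no ORF is claimed through
ambiguity).  Only sense frames are scanned because assembled transcripts
are stranded.  The 100-codon floor is the classical heuristic separating
annotated proteins from the short spurious ORFs random sequence yields
(random codons are stop-free with probability (61/64) per codon, so runs
of ≥ 100 are rare by chance); it is a proxy, not a trained classifier, and
a per-transcript `coding`/`noncoding` label file can override it, which is
the plug-in point for an external sequence-intrinsic predictor.  Loci that
fail the ORF test are `novel_antisense` if any isoform classified
antisense, else `novel_lincRNA`.  Novel loci receive ids
`NOVEL_LOC_%06d` in (chrom, start) order; matched loci inherit gene id,
name and biotype from the reference (missing biotypes become `unknown`
with a warning).

## Primer templates and picking

Junction-first: among junctions common to *all* isoforms of a gene, choose
the one maximizing the minimum flanking-exon length available in every
isoform — both primers must sit in sequence every isoform contains — with
ties broken toward the genomically first junction.  Up to `flank`
(default 150) bases are taken each side, so the default template is
≤ 300 bp and comfortably contains a 70–200 bp amplicon.  With no common
junction (any single-exon isoform forces this) the fallback is the longest
genomic interval exonic in every isoform, required to be ≥ 40 bp (two
~20-mers must fit).  Templates are in transcript orientation.

The built-in picker enumerates 18–24-mers with GC between 35–65% and
nearest-neighbour melting temperature 54–66 °C, then selects the pair
minimizing a score of Tm deviation from 60 °C, Tm imbalance and product
size, subject to: product 70–200 bp, primers non-overlapping, and — for
junction templates — the left primer ending strictly before and the right
primer starting strictly after the junction offset.  Thermodynamic
refinements (hairpins, dimers, salt correction beyond the Tm model) and
genome-wide specificity screening are out of scope; the engine is a
callable parameter, so a thermodynamic picker can be substituted
unchanged.

## Read preparation

The trimmer implements 3′-adapter semantics: scan positions left to right,
compare the adapter (truncated to the bases remaining, minimum overlap 3)
and truncate at the first position whose mismatch fraction is within
`max_mismatch_rate` (default 0.1; budget = floor(rate × compared length)).
Qualities are truncated in lockstep.  Trimming is idempotent once the
output is adapter-free; truncation can expose a new short adapter-prefix
suffix, which a repeat pass removes — the test suite checks the fixed
point is reached monotonically.  With a 3-base minimum overlap, roughly
1/64 of clean reads lose their last 3 bases to a chance match; that is the
standard sensitivity/precision trade-off at this setting, not an error.

Insert statistics: with adapters of length *a* on both fragment ends,
insert_mean = fragment_mean − 2a and insert_sd passes through unchanged
(adapter length is a constant; no variance model is assumed).  The mate
inner distance, insert_mean − 2 × read_len, may legitimately be negative
(overlapping mates) and is reported for aligner configuration.

## DE unification and concordance

Each tool's table is parsed by its own dialect (Cuffdiff `gene_exp.diff`;
edgeR `logFC/PValue/FDR`; DESeq2 `log2FoldChange/pvalue/padj`); a missing
required column raises an error naming it.  All three emit log2 fold
changes already, so normalization is a no-op beyond schema mapping.
Adjusted p-values are taken as emitted — the toolkit formats, it does not
re-correct.  `NA` FDRs become 1.0 with a flag (untestable, never
significant).  The unified table is sorted by (FDR, gene_id); the DE-only
GTF contains genes with FDR < α (default 0.05, conventional), and the DE
gene set is monotone in α.

Concordance of two fold-change vectors: Pearson r, r² and sign agreement
(fraction of pairs agreeing in direction, zero counted as positive).
Non-finite pairs — Cuffdiff emits ±inf for on/off genes — are excluded
with a warning; ≥ 3 finite pairs and nonzero variance are required.  On
the bundled validation panels the human and mouse r² values are stable
reference points; the rat panel's qRT-PCR column is on a visibly different
fold-change scale from its RNA-seq columns, so rat r² is reported but not
treated as a comparable quantity.

## Synthetic fixtures

The generator emulates a small multi-sample study: 2 chromosomes of
100 kb random sequence, 8 multi-exon reference genes (ENSEMBL-style
biotypes, some with an exon-skipping second isoform), and per-sample
assemblies containing exact reference copies plus planted truth — 3
intergenic multi-exon lincRNA loci, 2 opposite-strand loci overlapping
reference exons, 1 intergenic locus whose spliced sequence carries a
120-codon ORF written across its splice junction (codon-sampled without
stops, so the length is exact), and 5 single-exon noise transcripts
present in 1 of 4 samples.  Reads are 75-mers sampled from the genome with
the Illumina universal adapter appended to 30% at a random position ≥ 30;
counts are Poisson around group means with planted ±2 log2 fold changes;
DE tables are emitted in all three dialects.  Noncoding truth labels are
enforced: if a planted noncoding locus happens to draw a ≥ 100-codon ORF,
its sequence is re-rolled (bounded retries), keeping truth and genome
consistent.  A single NumPy generator keyed by the seed drives everything,
and outputs are byte-identical across runs.

What the fixture does **not** model: sequencing errors, coverage
non-uniformity, incomplete or fragmented assemblies, isoform-level
abundance structure, or genuine count dispersion.  Passing the end-to-end
tests therefore shows the *rules* are implemented correctly and
consistently, not that the pipeline is robust to assembler artifacts on
real data.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale by design: the
concordance panels are 6–8 genes; property suites use 100–200 random
instances (classification instances ≤ 50 transcripts, ORF sequences
≤ 3 kb); the end-to-end study is 2 × 100 kb with ~19 loci and 400 reads.
Floating-point comparisons round r² to two decimals when checked against
published values; all tie-breaks (junction choice, ORF start, novel-locus
ids, table sorts) are deterministic and documented above.
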