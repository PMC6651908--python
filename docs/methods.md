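# Methods

This note records, in one place, every algorithmic convention the
toolkit uses. Module references point to `src/asmeval/`.

## Coordinates and file formats (`core.py`, `intervals.py`)

All intervals are 0-based half-open `(start, end)` tuples. GFF3 input
(via `gffutils`) is converted from 1-based closed coordinates at the
boundary; FASTA/FASTQ go through Biopython. PSL records keep their
blocks in target order; for minus-strand query alignments the raw query
starts count from the query's reverse-complement end, so they are
normalized on read to the plus-strand frame as
`qstart = qsize - (raw_qstart + block_size)`. Interval arithmetic
(merge, intersect, union length, complement, projection of genomic
intervals onto spliced transcript coordinates) lives in `intervals.py`
and is the single primitive everything else builds on; merging also
joins adjacent (book-ended) intervals.

## Read QC and accounting (`qc.py`)

Read-pair filters, applied to a pair if either mate trips a rule:

- **adapter** — the adapter prefix matches an anchored suffix of the
  read covering ≥ 50 % of the adapter with at most one mismatch;
- **low quality** — strictly more than 10 % of bases below PHRED 10;
- **ambiguous** — strictly more than 1 % `N` bases.

Clean pairs are kept as *mapped* if their placement is convergent
(mates on opposite strands, leftmost mate on the plus strand) and the
span does not exceed the configured maximum. Duplicates are pairs that
share chromosome, both coordinates, and both strands; `deduplicate`
keeps the lexicographically smallest `pair_id` of each group and
returns the kept index. `StepReport` aggregates per-library counts;
platform-level percentages sum numerators and denominators across
libraries *before* dividing (not a mean of per-library percentages),
which is what makes the published table arithmetic reproduce exactly.

## Coverage versus depth (`coverage.py`)

Scaffold/genome alignments are filtered first: a scaffold is
**retained** when its best single alignment's summed block lengths
cover ≥ 98 % of the scaffold, **chimeric** when no single alignment
does but the merged union of all its alignments' query intervals does,
and **low quality** otherwise. Chimeras and low-quality scaffolds are
excluded from every downstream measurement.

Depth subsets are nested: one seeded permutation of pair ids is
truncated at each target base count, so a smaller subset is always a
subset of a larger one. Assembly itself is outside the toolkit's scope,
so subsets use a depth-threshold stand-in: the scaffolds of a
transcript enter a subset once the transcript's mean read depth in that
subset reaches `min_assembly_depth` (default 5×). For each subset the
curve reports unique genome bases covered by retained scaffolds
(merged target intervals) and the intersection of that union with the
annotated exon union; both tracks are also normalized by the largest
subset's exome value. `segment_slopes` returns the per-base slope of
the first and last curve segment, whose ratio distinguishes a
saturating track (ratio ≪ 1) from one still rising.

## Scaffold classification (`classify.py`)

For every retained scaffold the classifier records:

- **annotation fraction** — over all overlapping transcripts, the
  maximum of (overlap / scaffold aligned length) and (overlap /
  transcript spliced length); the threshold sweep counts a scaffold
  annotated at level *t* iff `fraction > t/100` (strict), so the
  annotated count is non-increasing in *t*;
- **single-exon** — an alignment block gap is called an intron when
  the target gap is ≥ 30 b while the query gap is ≤ 10 b; a scaffold
  with no such gap in its best alignment is single-exon;
- **intronic** — strictly more than 50 % of aligned target bases fall
  inside the intron union of annotated genes;
- **ORF** — six-frame scan for ATG→stop open reading frames of ≥ 100
  codons, evaluated on scaffolds ≥ 300 b.

## Completeness and library overlap (`completeness.py`)

Transcript completeness projects each retained scaffold's target
blocks onto every overlapping transcript's spliced coordinates. A
transcript is **complete** when one scaffold alone covers ≥ 95 % of
its spliced length. A scaffold whose two best transcript scores tie
exactly is ambiguous and contributes to no transcript. Between-library
agreement is the matrix `M[a, b] = |complete(a) ∩ complete(b)| /
|complete(a)|` (rows normalized by the row library).

## GC bias (`gcbias.py`)

Transcript selection for the windowed curve: single-copy transcripts
whose genomic footprint overlaps no other transcript and whose mean
depth is ≥ 10× in every compared dataset. A Spearman correlation
between the GC histogram of the selected set and of all transcripts
guards against the selection itself skewing composition. Per
transcript, non-overlapping 100 b windows (trailing partial discarded)
get a ratio = window mean depth / transcript mean depth; ratios are
binned by window GC (percent) and averaged per bin. An unbiased
dataset gives a flat curve at 1; composition bias appears as a
monotone tilt matching the injected/underlying fragment-selection
weight up to renormalization by the window-weighted mean.

Abundance comparison: TPM from unambiguous pair counts with effective
length `max(L − fragment + 1, 1)`, scaled to 10⁶. For transcripts with
TPM ≥ 10 in both libraries, ordinary least squares of
`log10(TPM_a / TPM_b)` on transcript GC returns slope, standard error,
and the included fraction. Gap analysis (`gap_regions`) reports, for a
transcript, regions covered by neither scaffolds nor reads, and
`gc_cumulants` gives length-weighted GC CDFs of such regions for
comparison across platforms.

## Synthetic data (`synth.py`)

The generator builds a genome of gene loci (exons/introns separated by
intergenic spacers) with optional unannotated transcripts placed in
introns or intergenic gaps, per-segment GC controlled by stratified
permutation of fixed-GC 100 b blocks within 2.5 kb segments.
Transcript abundances are exponential; fragments are sampled by
abundance, length-normal, and optionally thinned by a fragment-level
GC acceptance weight (rejection sampling) to inject composition bias.
Reads inherit exact coordinates, so ground truth (duplicate flags,
per-transcript depth, GC, abundance) is known. Truth scaffolds are one
per transcript (optionally truncated for incompleteness studies), and
chimeras are concatenations of two transcripts; PSL alignments are
emitted directly from the generating coordinates. Presets fix
parameter regimes for the depth-curve, completeness, and GC-bias
studies; all randomness flows from a single integer seed through
per-stage child generators.

## Bundled benchmark tables (`benchmark_data.py`)

Static per-library read-accounting, filter-category, and
completeness-by-depth tables from a published two-platform
(DNBseq/HiSeq) benchmark of a reference RNA sample, with accessors
returning tidy DataFrames. These support exact reproduction of the
printed aggregate percentages and internal-consistency checks (step
monotonicity, category sums, combined-assembly dominance).
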