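# Methods

## Problem and model

Cytoplasmic RNA fractions (dissected dendrites, single-cell somas, whole
tissue) yield uniquely mapping read pairs inside annotated introns. The
working model is that for a minority of introns, a short (~350–400 nt)
sub-sequence is retained in mature cytoplasmic transcripts. Detection
therefore has three parts: locating intronic read islands, rejecting
alternative explanations for intronic signal, and characterizing what
survives.

All coordinates are 0-based half-open genomic intervals; GTF input
(1-based inclusive) is converted at parse time. Intron indices count
5'→3' in transcription order, so intron 1 of a minus-strand gene is the
rightmost gap in genome coordinates. The counting unit everywhere is the
*fragment* (a mate pair counted once, all aligned blocks of both mates
pooled into one footprint), since paired-end evidence is one observation
of one molecule; a per-read mode is not provided.

## Fragment classification

A unique fragment is **exonic** when every block lies in the exon union of
exactly one gene, **intronic** when every block lies within one intron,
and an **exon–intron junction** fragment when its blocks touch both exon
and intron space of one gene (assigned to the intron with the largest
overlap). Fragments overlapping no gene span are **intergenic**; fragments
overlapping several genes, or only the 1-kb padded flank of a gene, are
**ambiguous** and excluded from all statistics but counted. The 1-kb pad
(configurable) keeps unannotated-UTR bleed out of the intergenic tally;
the same padded complement defines the intergenic territory used by the
enrichment test.

**Enrichment test.** Whether intronic reads exceed intergenic background
is a two-sample rate comparison on (reads, territory nt) pairs. Small
samples (≤ 500 total reads) use the exact conditional form: under equal
per-base rates, the intronic count given the total is
Binomial(n, nt_in/(nt_in+nt_ig)), and the one-sided tail is exact. Larger
samples use the pooled two-proportion z-test. Both routes are exposed via
`method=`.

## Contig assembly

Within one intron, fragment footprints are sorted and merged by single
linkage whenever the inter-footprint gap is ≤ 500 bp ("separated by no
more than 500 bp" — the boundary gap of exactly 500 merges). The 500-bp
scale absorbs mappability holes from intronic repeats and is roughly two
back-to-back paired-end fragments. Contigs are clipped to the intron;
exon–intron junction fragments never extend a contig but set a boolean
`has_exon_junction_end` when they overlap or abut (half-open adjacency
counts) a contig end. The pA-tract analogue clusters A-runs ≥ 9 nt at
gaps strictly < 500 bp; the two boundary conventions intentionally differ
because each follows its own stated rule.

**Length null test.** If sequenced intervals arose from uniformly random
breaks, island lengths would be approximately exponential. Contig lengths
are KS-tested against an exponential with rate 1/mean(lengths). Because
the rate is estimated from the same data, the nominal p-value is
conservative (calibration is verified by simulation in the test suite:
empirical rejection at α = 0.05 stays below 0.05).

**ORF screen.** An ORF is ATG-initiated and ends at the first in-frame
stop or at the sequence end (an open 3' end counts; a stop-to-stop mode is
deliberately not the default because contig boundaries are sequencing
artifacts, not biological ends). Reported length in aa excludes the stop.
Codons containing N are neither start nor stop. Six frames: three on the
given sequence, three on its reverse complement.

**Positional analyses.** A contig is assigned to an intron third by its
5'-most base on the transcribed strand, with thirds split at floor(L/3)
and floor(2L/3). The 5'/3'-half analysis pools genes with ≥ 5 introns:
intron index ≤ floor(n/2) is the 5' half, the odd middle intron
(index (n+1)/2 for odd n) is excluded, the rest is the 3' half.

## Filter cascade

Five optional stages flag (never delete) candidate introns; a call passes
iff no flag is set, and only passed calls feed the summary statistics.
Predicted-gene and poly(A)-site filters act at the intron level (a ≥1-base
interval overlap, resp. point containment); ncRNA and antisense filters
act at the contig level and propagate to the intron, recording the
overlapped annotation for the ncRNA class breakdown. An intron supported
only by junction fragments is flagged `junction_only` (possible
unannotated exon extension). All predicates are strand-blind because the
assumed library protocol is unstranded. Stages with missing annotation
files are skipped with a warning — the reference resources are external.
The stages are pure interval predicates, so the cascade commutes and is
monotone in its annotation inputs (both property-tested).

Assembly happens before filtering: flags annotate calls rather than
removing reads, which keeps every decision auditable in the output table.

## Sample modes

* `dendrite` — full cascade, no length cutoff (nucleus-free sample).
* `soma` (whole cell) — additionally drops contigs > 400 nt, since hnRNA
  contamination inflates contig lengths; introns left with no contig lose
  their call.
* `tissue` — total RNA: junction-only flagging and the length cutoff are
  both disabled; repeat filtering is available as a separate step.

## Junction discovery

From a de-novo junction table (chrom, start, end, signal, unique reads,
overhangs), a junction is accepted when its splice signal is in
{GT-AG, GC-AG, AT-AC} or a reverse complement, it has ≥ 1 unique crossing
read with ≥ 8 bp on each side, and donor and acceptor are both strictly
inside one annotated intron. Junctions overlapping an intron but crossing
an annotated boundary are ordinary splicing and are counted separately.
Validation-candidate selection additionally requires host intron
< 20 kb, spliced-out length ≥ 100 bp, host-gene expression above the
sample median, and no homopolymer run ≥ 10 nt within 50 nt of either side
— the homopolymer screen is this package's operationalization of "sequence
complexity adequate for primer design", for which no standard formula
exists.

## Matched background set

For each retained intron, one intron is drawn uniformly (seeded,
without replacement) from genes with zero passed calls, subject to:
|ΔGC| ≤ 5 percentage points, length within ±5% relative, and identical
maximal internal pA-tract length (tracts shorter than 10 nt count as 0 =
"no tract"). The "within 5%" windows are stated ambiguously in common
usage; percentage points for GC and relative for length were chosen and
both are configurable. Introns with no admissible candidate are returned
as unmatched, never dropped silently. Matching without replacement keeps
the background size-matched and duplicate-free.

## Synthetic data generator

The generator emulates the structure of a subcellular RNA-seq sample, not
its sequencing chemistry: fragments are emitted as already-aligned
footprints (the pipeline contract starts at alignments), with no error
model, duplicates, or quality scores.

Defaults are the study conditions of the subcellular survey the pipeline
is built for: intron lengths lognormal with median 1300 nt (σ = 0.8,
capped at 20 kb to keep desk-scale genomes ~3 Mb); 2–10 introns per gene;
exons 100–250 nt; half of genes carry one retained intron; retained
segment lengths Normal(360, 60) truncated above the 50-nt read length;
20× exonic and intronic (over the segment) coverage; 47% of introns carry
a planted internal pA tract of 10–14 nt; 30% of retained segments abut an
exon boundary and emit junction-straddling fragments; intergenic noise at
0.02× held > 1 kb away from gene spans; hnRNA coverage 0 (dendrite) or
positive (soma/tissue). Decoy annotations (ncRNA, poly(A) site, predicted
gene, antisense) each overlap a disjoint known subset of planted introns;
planted junction tables contain both quality-passing junctions and decoys
(short overhang, disallowed signal, boundary-crossing).

Two seeds control generation: `structure_seed` fixes the genome, gene
models and pA tracts, `seed` fixes retention choices and read sampling, so
replicate samples can share one reference like biological replicates do.
All per-intron truth (pA length, segment, decoy flags) is recomputed from
the final sequence, so accidental A-runs in the random genome cannot
desynchronize the truth table. Same config + seed reproduces every output
file byte for byte.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: mappability holes and repeat-driven
multi-mapping, amplification 3' bias (a positional-bias knob exists but
defaults off), overlapping genes, alternative isoforms, expression-level
heterogeneity across genes, and alignment errors. Recovery results on
synthetic data are statements about the pipeline's correctness, not about
sensitivity on any particular tissue.

## Numerical and edge-case conventions

* GC fraction excludes N from numerator and denominator; all-N sequences
  give NaN.
* Features shorter than the 50-bp density window form a single window.
* Correlations return NaN for n < 3 or constant vectors.
* The KS test requires ≥ 8 lengths.
* Empty fragment sets assemble to empty contig lists; zero reads in both
  territories give enrichment p = 1.
* Single-intron genes sit at normalized position 0.5 in the
  intron-position histogram.
* Replicate overlap uses the min-set denominator
  |A∩B| / min(|A|, |B|); the Jaccard form is reported alongside since
  "overlap" has no canonical denominator.
* Acceptance-script problem sizes: three replicates of 200 genes at 20×
  depth (~50k fragments each), chosen so the whole analysis reruns in
  seconds while every statistic still has n ≥ 80 supporting observations.

## Known limitations

* Transcript models are analyzed independently; overlapping transcripts
  of one gene are rolled up per gene id at reporting time only.
* Contigs never span exon–intron boundaries; junction evidence survives
  only as the end flag.
* The intergenic pad trades a small loss of genuinely intergenic reads
  (classified ambiguous) for robustness against UTR misannotation.
* ID/SINE-element counting inside junctions requires a user-supplied
  repeat BED; no repeat library ships with the package.
* GO enrichment is out of scope; the high-count gene list is exported
  ranked for external tools.
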