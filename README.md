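# cirtseq

Detection and characterization of **Cytoplasmic Intron-sequence Retaining
Transcripts (CIRTs)** from subcellular RNA-seq alignments.

Subcellular RNA sequencing — of mechanically dissected neuronal dendrites,
single-cell somas, or whole tissue — consistently shows uniquely mapping
read pairs inside annotated introns. When the sample is nucleus-free
cytoplasm, such reads cannot be dismissed as unspliced pre-mRNA (hnRNA):
they are evidence that short sub-sequences of specific introns are retained
in mature cytoplasmic transcripts, where they may carry localization or
regulatory signals. `cirtseq` is for computational biologists who want to
detect such retention from aligned reads, separate it from the many
confounders that mimic it, and characterize the retained sequence.

## What it computes

Starting from uniquely aligned paired-end fragments and gene models, the
pipeline:

1. **Classifies** each fragment as exonic, intronic, exon–intron junction,
   intergenic, or ambiguous, and tests per-base intronic enrichment over
   intergenic background with a one-sided two-proportion binomial test
   (exact conditional form for small counts).
2. **Assembles contigs**: intronic footprints in one intron are
   single-linkage clustered, merging footprints separated by ≤ 500 bp. The
   contig — a coverage island — is the unit of retention evidence. Against
   the null of uniformly random fragment starts and ends (which yields
   exponentially distributed island lengths, rate 1/mean), observed contig
   lengths are tested with a Kolmogorov–Smirnov statistic.
3. **Filters** candidate retained introns through five annotation-based
   stages, each a ≥1-base overlap predicate: predicted genes, intronic
   poly(A) sites, ncRNAs, antisense transcripts, and junction-only introns
   (introns whose only reads straddle an exon–intron boundary). An intron
   passing all stages with ≥ 1 contig is a retained-intron call.
4. **Characterizes** calls: six-frame ORF and stop-codon screens of contig
   sequences, intron-position frequencies along the gene model, 5'/3'-half
   proportions, pA-tract contigs (A-runs ≥ 9 nt clustered at gaps < 500
   bp), repeat and EST overlap classes, replicate overlaps and the shared
   confident intron set, and read-count threshold sweeps.
5. **Discovers intron-internal junctions**: de-novo junction calls whose
   donor and acceptor both fall strictly inside one annotated intron, with
   a known splice signal (GT-AG / GC-AG / AT-AC and reverse complements),
   ≥ 1 unique crossing read and ≥ 8 bp overhang on each side.
6. **Samples a matched background intron set**: for each retained intron,
   one intron from a retention-free gene with length within ±5%, GC within
   5 percentage points, and an identical internal pA-tract length.

A fully seeded synthetic-data generator (`cirtseq.synthetic_data`) plants
ground-truth CIRTs, decoys, and junctions in a random genome, so the whole
pipeline is testable offline against a machine-readable truth table.

## Worked example

```python
from cirtseq import SimConfig, simulate, run_pipeline

res = simulate(SimConfig(seed=1, n_genes=200, cirt_gene_fraction=0.3))
pr = run_pipeline(
    res.models, res.fragments,
    chrom_lengths=res.chrom_lengths,
    ncrnas=res.decoys["ncRNA"], polya_sites=res.decoys["polyA_site"],
    predicted_genes=res.decoys["predicted_gene"], antisense=res.decoys["antisense"],
)
expected = {g for g, _ in res.truth.clean_retained_keys()}
print(len(pr.cirt_genes), "CIRT genes detected;",
      len(expected & pr.cirt_genes), "match the planted truth")
import numpy as np
print("mean contig length:", np.mean([c.length for c in pr.passed_contigs]))
print("intronic enrichment p:", pr.enrichment_p)
```

prints

```
40 CIRT genes detected; 40 match the planted truth
mean contig length: 350.1
intronic enrichment p: 1.1920768625396976e-79
```

i.e. every gene with a cleanly planted retained segment (60 planted, 20 of
which overlap annotation decoys and are correctly filtered out) is
recovered, with no false positives; the mean assembled contig length
recovers the configured 360 ± 60 nt retained-segment length; and intronic
read density is overwhelmingly enriched over intergenic background.

The same works from the shell:

```sh
cirtseq simulate --seed 1 --n-genes 200 --out sim/
cirtseq run --fragments sim/fragments.bed --annotation sim/genes.bed \
    --ncrna sim/decoy_ncRNA.bed --out run/
```

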