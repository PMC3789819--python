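"""End-to-end orchestration: classify fragments, assemble contigs, apply the
filter cascade, and summarize.

Modes mirror the sample types:

* ``dendrite`` — dissected cytoplasm, no hnRNA expected: full filter
  cascade, no contig length cutoff.
* ``soma`` (whole cell) — full cascade plus the <=400 nt contig length
  cutoff to minimize hnRNA contamination.
* ``tissue`` — total RNA: junction-only introns are kept and no length
  cutoff is applied; repeat filtering is available separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from cirtseq.annotation import GeneModel, IntronRecord
from cirtseq.cirt_filters import RetainedIntronCall, apply_filter_cascade, build_calls
from cirtseq.contig_assembly import (
    SOMA_MAX_CONTIG_LEN,
    apply_length_cutoff,
)
from cirtseq.read_classification import (
    AnnotationIndex,
    FragmentAssignment,
    ReadAlignment,
    classify_fragments,
    enrichment_test,
)
from cirtseq.reporting import GeneCirtSummary, summarize_genes

MODES = ("dendrite", "soma", "tissue")


@dataclass
class PipelineResult:
    mode: str
    assignments: list[FragmentAssignment]
    calls: list[RetainedIntronCall]
    gene_summaries: list[GeneCirtSummary]
    category_counts: dict[str, int]
    enrichment_p: float

    @property
    def passed_calls(self) -> list[RetainedIntronCall]:
        return [c for c in self.calls if c.passed]

    @property
    def cirt_genes(self) -> set[str]:
        return {c.gene_id for c in self.passed_calls}

    @property
    def passed_contigs(self) -> list:
        return [ctg for c in self.passed_calls for ctg in c.contigs]


def run_pipeline(
    models: Sequence[GeneModel],
    fragments: Sequence[ReadAlignment],
    *,
    mode: str = "dendrite",
    chrom_lengths: Mapping[str, int] | None = None,
    gap_threshold: int = 500,
    max_contig_len: int = SOMA_MAX_CONTIG_LEN,
    predicted_genes=None,
    polya_sites=None,
    ncrnas=None,
    antisense=None,
    classifier_pad: int = 1000,
) -> PipelineResult:
    """Run classification -> contig assembly -> filtering -> summaries."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    index = AnnotationIndex(models, pad=classifier_pad)
    assignments = classify_fragments(fragments, index)
    counts = {c: 0 for c in ("exonic", "intronic", "exon_intron_junction", "intergenic", "ambiguous")}
    for a in assignments:
        counts[a.category] += 1

    aln_by_id = {f.fragment_id: f for f in fragments}
    calls = build_calls(
        assignments, aln_by_id, index.introns, gap_threshold=gap_threshold
    )

    if mode == "soma":
        for call in calls:
            call.contigs = apply_length_cutoff(call.contigs, max_contig_len)
        # introns whose every contig exceeded the cutoff no longer carry
        # retention evidence (junction-only candidates keep their call so
        # the cascade can flag them)
        calls = [c for c in calls if c.contigs or c.n_internal_fragments == 0]
    calls = apply_filter_cascade(
        calls,
        predicted_genes=predicted_genes,
        polya_sites=polya_sites,
        ncrnas=ncrnas,
        antisense=antisense,
        exclude_junction_only=(mode != "tissue"),
    )
    passed = [c for c in calls if c.passed and c.contigs]
    model_map = {m.gene_id: m for m in models}
    summaries = summarize_genes(assignments, passed, model_map)

    enrichment_p = float("nan")
    if chrom_lengths is not None:
        intron_nt = sum(
            it.length for its in index.introns.values() for it in its
        )
        intergenic_nt = index.intergenic_length(dict(chrom_lengths))
        intronic_reads = counts["intronic"]
        intergenic_reads = counts["intergenic"]
        if intron_nt > 0 and intergenic_nt > 0:
            enrichment_p = enrichment_test(
                (intronic_reads, intron_nt), (intergenic_reads, intergenic_nt)
            )

    return PipelineResult(
        mode=mode,
        assignments=assignments,
        calls=calls,
        gene_summaries=summaries,
        category_counts=counts,
        enrichment_p=enrichment_p,
    )
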