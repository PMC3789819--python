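"""Filtering cascade for candidate retained introns.

Intronic reads in a cytoplasmic sample can come from sources other than
retained intron sequence: cryptic predicted genes, intronic poly(A)-site
driven transcripts, independently transcribed ncRNAs, antisense
transcription, and unannotated exon extensions (junction-only introns).
Each stage flags (never deletes) a candidate call; a call passes when no
flag is set.  All overlap predicates are strand-blind (the library protocol
is not strand specific) and use the single-base overlap rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from cirtseq.annotation import IntronRecord
from cirtseq.contig_assembly import Contig, assemble_contigs
from cirtseq.read_classification import FragmentAssignment, ReadAlignment

log = logging.getLogger(__name__)

Interval = tuple[int, int]
Bed = Sequence[tuple[str, int, int]]

FILTER_STAGES = ("predicted_gene", "polyA_site", "ncRNA", "antisense", "junction_only")


@dataclass
class RetainedIntronCall:
    """One candidate retained intron with its contigs and filter flags."""

    gene_id: str
    intron_index: int
    chrom: str
    intron_interval: Interval
    contigs: list[Contig]
    n_internal_fragments: int
    n_junction_fragments: int
    filter_flags: set[str] = field(default_factory=set)
    ncrna_hits: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.filter_flags

    @property
    def total_intronic_fragments(self) -> int:
        return sum(c.n_fragments for c in self.contigs)

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene_id, self.intron_index)


def build_calls(
    assignments: Sequence[FragmentAssignment],
    alignments: Mapping[str, ReadAlignment],
    introns_by_gene: Mapping[str, Sequence[IntronRecord]],
    gap_threshold: int = 500,
) -> list[RetainedIntronCall]:
    """Group intronic and exon-intron-junction fragments per (gene, intron),
    assemble contigs, and emit one candidate call per intron with evidence."""
    internal: dict[tuple[str, int], list[ReadAlignment]] = {}
    junction: dict[tuple[str, int], list[ReadAlignment]] = {}
    for a in assignments:
        if a.category not in ("intronic", "exon_intron_junction"):
            continue
        key = (a.gene_id, a.intron_index)
        bucket = internal if a.category == "intronic" else junction
        bucket.setdefault(key, []).append(alignments[a.fragment_id])
    calls = []
    for key in sorted(set(internal) | set(junction)):
        gene_id, idx = key
        intron = next(
            it for it in introns_by_gene[gene_id] if it.intron_index == idx
        )
        contigs = assemble_contigs(
            internal.get(key, []),
            gap_threshold=gap_threshold,
            gene_id=gene_id,
            intron_index=idx,
            intron_interval=intron.interval,
            chrom=intron.chrom,
            junction_fragments=junction.get(key, []),
        )
        calls.append(
            RetainedIntronCall(
                gene_id=gene_id,
                intron_index=idx,
                chrom=intron.chrom,
                intron_interval=intron.interval,
                contigs=contigs,
                n_internal_fragments=len(internal.get(key, [])),
                n_junction_fragments=len(junction.get(key, [])),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# stages


def _interval_overlaps(chrom: str, iv: Interval, bed: Bed) -> list[tuple[str, int, int]]:
    s, e = iv
    return [(c, bs, be) for c, bs, be in bed if c == chrom and bs < e and s < be]


def filter_predicted_genes(call: RetainedIntronCall, predicted: Bed) -> RetainedIntronCall:
    """Flag when the intron overlaps any predicted-gene interval by >= 1 base
    (gene-prediction output consumed as intervals)."""
    if _interval_overlaps(call.chrom, call.intron_interval, predicted):
        call.filter_flags.add("predicted_gene")
    return call


def filter_polya_sites(
    call: RetainedIntronCall, sites: Sequence[tuple[str, int]]
) -> RetainedIntronCall:
    """Flag when any annotated poly(A) site (point coordinate) falls inside
    the intron (half-open containment)."""
    s, e = call.intron_interval
    if any(c == call.chrom and s <= pos < e for c, pos in sites):
        call.filter_flags.add("polyA_site")
    return call


def filter_ncrna(call: RetainedIntronCall, ncrnas: Bed) -> RetainedIntronCall:
    """Flag when any contig overlaps an annotated ncRNA by even a single
    base; the hits are recorded for the ncRNA class breakdown."""
    for contig in call.contigs:
        hits = _interval_overlaps(call.chrom, contig.interval, ncrnas)
        if hits:
            call.filter_flags.add("ncRNA")
            call.ncrna_hits.extend(hits)
    return call


def filter_antisense(call: RetainedIntronCall, antisense: Bed) -> RetainedIntronCall:
    """Flag when any contig has at least a partial (>= 1 base) overlap with
    an antisense transcript interval."""
    for contig in call.contigs:
        if _interval_overlaps(call.chrom, contig.interval, antisense):
            call.filter_flags.add("antisense")
            break
    return call


def filter_junction_only(call: RetainedIntronCall) -> RetainedIntronCall:
    """Flag introns whose only supporting reads straddle exon-intron
    junctions: those may be unannotated exon extensions, not retention."""
    if call.n_internal_fragments == 0 and call.n_junction_fragments > 0:
        call.filter_flags.add("junction_only")
    return call


def apply_filter_cascade(
    calls: Iterable[RetainedIntronCall],
    *,
    predicted_genes: Bed | None = None,
    polya_sites: Sequence[tuple[str, int]] | None = None,
    ncrnas: Bed | None = None,
    antisense: Bed | None = None,
    exclude_junction_only: bool = True,
) -> list[RetainedIntronCall]:
    """Run all provided stages over the calls.

    Stages with missing annotation inputs are skipped with a warning
    (external annotation resources are optional).  The stages are pure
    interval predicates, so their order does not matter.
    """
    calls = list(calls)
    stages = [
        ("predicted_gene", predicted_genes, filter_predicted_genes),
        ("polyA_site", polya_sites, filter_polya_sites),
        ("ncRNA", ncrnas, filter_ncrna),
        ("antisense", antisense, filter_antisense),
    ]
    for name, annot, fn in stages:
        if annot is None:
            log.warning("no annotation for %s filter — stage skipped", name)
            continue
        for call in calls:
            fn(call, annot)
    if exclude_junction_only:
        for call in calls:
            filter_junction_only(call)
    return calls


def write_calls_tsv(calls: Iterable[RetainedIntronCall], path) -> None:
    with open(path, "w") as out:
        cols = "\t".join(FILTER_STAGES)
        out.write(
            f"gene_id\tintron_index\tchrom\tstart\tend\tn_contigs\t"
            f"n_fragments\t{cols}\tpassed\n"
        )
        for c in calls:
            flags = "\t".join(str(int(f in c.filter_flags)) for f in FILTER_STAGES)
            s, e = c.intron_interval
            out.write(
                f"{c.gene_id}\t{c.intron_index}\t{c.chrom}\t{s}\t{e}\t"
                f"{len(c.contigs)}\t{c.total_intronic_fragments}\t{flags}\t"
                f"{int(c.passed)}\n"
            )
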