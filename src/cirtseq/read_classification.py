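"""Fragment classification and density / enrichment statistics.

Uniquely mapped paired-end fragments (both mates pooled into one footprint
of aligned blocks) are assigned to exonic / intronic / exon-intron-junction
/ intergenic categories against an interval index of the gene models.
Non-unique fragments are dropped upstream and counted.  The counting unit
is the fragment, so paired evidence is counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from cirtseq.annotation import GeneModel, IntronRecord, derive_introns

log = logging.getLogger(__name__)

Interval = tuple[int, int]

CATEGORIES = ("exonic", "intronic", "exon_intron_junction", "intergenic", "ambiguous")


@dataclass
class ReadAlignment:
    """One uniquely aligned paired-end fragment.

    ``blocks`` holds the aligned genomic intervals of both mates, including
    spliced sub-blocks, sorted by start.
    """

    fragment_id: str
    chrom: str
    blocks: list[Interval]
    unique: bool = True

    def __post_init__(self) -> None:
        self.blocks = sorted((int(s), int(e)) for s, e in self.blocks)

    @property
    def footprint(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])


@dataclass
class FragmentAssignment:
    fragment_id: str
    category: str
    gene_id: str | None = None
    intron_index: int | None = None


class AnnotationIndex:
    """Per-chromosome interval trees over gene spans, with per-gene exon
    unions and introns for containment tests.

    ``pad`` widens every gene span on both sides when delimiting intergenic
    space, so that reads just beyond an annotated terminus (UTR bleed) are
    not counted as intergenic signal.
    """

    def __init__(self, models: Sequence[GeneModel], pad: int = 1000):
        self.models = {m.gene_id: m for m in models}
        self.pad = pad
        self.introns: dict[str, list[IntronRecord]] = {
            m.gene_id: derive_introns(m) for m in models
        }
        self._span_tree: dict[str, IntervalTree] = {}
        self._pad_tree: dict[str, IntervalTree] = {}
        for m in models:
            s, e = m.span
            self._span_tree.setdefault(m.chrom, IntervalTree()).addi(s, e, m.gene_id)
            self._pad_tree.setdefault(m.chrom, IntervalTree()).addi(
                max(0, s - pad), e + pad, m.gene_id
            )

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        tree = self._span_tree.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def in_padded_zone(self, chrom: str, start: int, end: int) -> bool:
        tree = self._pad_tree.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def intergenic_length(self, chrom_lengths: dict[str, int]) -> int:
        """Total nt outside all padded gene spans (the intergenic territory)."""
        total = 0
        for chrom, clen in chrom_lengths.items():
            tree = self._pad_tree.get(chrom)
            covered = 0
            if tree is not None:
                merged = tree.copy()
                merged.merge_overlaps()
                covered = sum(min(iv.end, clen) - max(iv.begin, 0) for iv in merged)
            total += clen - covered
        return total


def _blocks_within(blocks: Sequence[Interval], intervals: Sequence[Interval]) -> bool:
    """True iff every block is contained in some interval of the sorted list."""
    for bs, be in blocks:
        ok = any(s <= bs and be <= e for s, e in intervals)
        if not ok:
            return False
    return True


def _overlap_nt(blocks: Sequence[Interval], interval: Interval) -> int:
    s, e = interval
    return sum(max(0, min(be, e) - max(bs, s)) for bs, be in blocks)


def _classify_against_gene(
    aln: ReadAlignment, model: GeneModel, introns: Sequence[IntronRecord]
) -> tuple[str, int | None]:
    """Category of a fragment relative to one gene, assuming span overlap."""
    if _blocks_within(aln.blocks, model.exons):
        return "exonic", None
    for it in introns:
        if _blocks_within(aln.blocks, [it.interval]):
            return "intronic", it.intron_index
    # touches both exon union and intron space of this gene -> junction;
    # assign the intron with the largest overlap
    exon_nt = sum(_overlap_nt(aln.blocks, ex) for ex in model.exons)
    best, best_nt = None, 0
    for it in introns:
        nt = _overlap_nt(aln.blocks, it.interval)
        if nt > best_nt:
            best, best_nt = it.intron_index, nt
    if exon_nt > 0 and best is not None:
        return "exon_intron_junction", best
    if best is not None:
        # intronic overlap only, but not contained in a single intron
        # (e.g. spanning a tiny internal exon) — treat as junction evidence
        return "exon_intron_junction", best
    return "ambiguous", None


def classify_fragment(aln: ReadAlignment, index: AnnotationIndex) -> FragmentAssignment:
    """Assign one unique fragment to a category.

    Exonic / intronic require all blocks within the exon union / within one
    intron of a single gene; straddling an exon-intron boundary gives
    ``exon_intron_junction``.  Fragments overlapping no gene span are
    intergenic (those inside the padded flanks are ambiguous, to keep UTR
    bleed out of the intergenic tally); fragments overlapping several genes
    with conflicting assignments are ambiguous and excluded downstream.
    """
    s, e = aln.footprint
    gene_ids = index.genes_overlapping(aln.chrom, s, e)
    if not gene_ids:
        if index.in_padded_zone(aln.chrom, s, e):
            return FragmentAssignment(aln.fragment_id, "ambiguous")
        return FragmentAssignment(aln.fragment_id, "intergenic")
    results = [
        (gid, _classify_against_gene(aln, index.models[gid], index.introns[gid]))
        for gid in gene_ids
    ]
    results = [(gid, cat, idx) for gid, (cat, idx) in results if cat != "ambiguous"]
    if not results:
        return FragmentAssignment(aln.fragment_id, "ambiguous")
    if len({(cat, idx) for _, cat, idx in results}) > 1 or len(results) > 1:
        # multiple genes claim the fragment
        return FragmentAssignment(aln.fragment_id, "ambiguous")
    gid, cat, idx = results[0]
    return FragmentAssignment(aln.fragment_id, cat, gene_id=gid, intron_index=idx)


def classify_fragments(
    alignments: Iterable[ReadAlignment], index: AnnotationIndex
) -> list[FragmentAssignment]:
    """Classify all unique fragments; non-unique ones are dropped and counted."""
    out = []
    n_nonunique = 0
    for aln in alignments:
        if not aln.unique:
            n_nonunique += 1
            continue
        out.append(classify_fragment(aln, index))
    if n_nonunique:
        log.info("dropped %d non-unique fragments", n_nonunique)
    return out


# ---------------------------------------------------------------------------
# density


@dataclass
class DensityProfile:
    feature_id: str
    window_size: int
    counts: np.ndarray
    median_density: float = field(init=False)
    max_density: int = field(init=False)

    def __post_init__(self) -> None:
        self.median_density = float(np.median(self.counts))
        self.max_density = int(np.max(self.counts))


def density_profile(
    fragments: Sequence[ReadAlignment],
    feature: Interval,
    window: int = 50,
    feature_id: str = "",
) -> DensityProfile:
    """Fragments overlapping each ``window``-nt tiling window of a feature.

    A feature shorter than the window is a single window.  Counts are per
    fragment (mate pairs once).
    """
    start, end = feature
    length = end - start
    n_win = max(1, -(-length // window))
    counts = np.zeros(n_win, dtype=int)
    for frag in fragments:
        fs, fe = frag.footprint
        fs, fe = max(fs, start), min(fe, end)
        if fe <= fs:
            continue
        w0 = (fs - start) // window
        w1 = (fe - 1 - start) // window
        counts[w0 : w1 + 1] += 1
    return DensityProfile(feature_id=feature_id, window_size=window, counts=counts)


# ---------------------------------------------------------------------------
# intronic-vs-intergenic enrichment


def enrichment_test(
    intronic: tuple[int, int],
    intergenic: tuple[int, int],
    method: str = "auto",
) -> float:
    """One-sided test that the per-base intronic read rate exceeds the
    intergenic rate.

    Each argument is ``(reads, total_nt)``.  Conditional on the total read
    count, the intronic count is Binomial(n, nt_intronic / nt_total) under
    equal per-base rates, giving an exact one-sided p-value
    (``method='exact'``); the large-sample route is the pooled two-sample
    proportion z-test.  ``auto`` uses the exact test up to 500 total reads.
    """
    x1, n1 = intronic
    x2, n2 = intergenic
    if n1 <= 0 or n2 <= 0:
        raise ValueError("territory sizes must be positive")
    if x1 + x2 == 0:
        return 1.0
    if method == "auto":
        method = "exact" if x1 + x2 <= 500 else "normal"
    if method == "exact":
        p_null = n1 / (n1 + n2)
        return float(stats.binom.sf(x1 - 1, x1 + x2, p_null))
    if method == "normal":
        p1, p2 = x1 / n1, x2 / n2
        pool = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        if se == 0:
            return 1.0
        z = (p1 - p2) / se
        return float(stats.norm.sf(z))
    raise ValueError(f"unknown method: {method}")


# ---------------------------------------------------------------------------
# readers


def read_fragments_bed12(path: str | Path) -> list[ReadAlignment]:
    """Read fragments from a BED12-like table (one line per fragment, both
    mates' blocks in blockSizes/blockStarts; score column 1 = unique)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom, start, name, score = f[0], int(f[1]), f[3], f[4]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            out.append(
                ReadAlignment(
                    fragment_id=name, chrom=chrom, blocks=blocks, unique=score != "0"
                )
            )
    return out


def read_fragments_bam(
    path: str | Path, min_mapq: int = 10
) -> list[ReadAlignment]:
    """Read paired fragments from a coordinate-sorted indexed BAM.

    A fragment is unique when both mates have MAPQ >= ``min_mapq`` and
    neither carries a multi-hit tag (NH > 1).  Mates are paired by query
    name; spliced alignments contribute one block per aligned segment.
    """
    import pysam

    frags: dict[str, ReadAlignment] = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            unique = read.mapping_quality >= min_mapq and (
                not read.has_tag("NH") or read.get_tag("NH") <= 1
            )
            blocks = [(s, e) for s, e in read.get_blocks()]
            key = read.query_name
            if key in frags:
                prev = frags[key]
                prev.blocks = sorted(prev.blocks + blocks)
                prev.unique = prev.unique and unique
            else:
                frags[key] = ReadAlignment(
                    fragment_id=key,
                    chrom=read.reference_name,
                    blocks=blocks,
                    unique=unique,
                )
    return list(frags.values())


def write_assignments_tsv(
    assignments: Iterable[FragmentAssignment], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("fragment_id\tcategory\tgene_id\tintron_index\n")
        for a in assignments:
            out.write(
                f"{a.fragment_id}\t{a.category}\t{a.gene_id or '.'}\t"
                f"{a.intron_index if a.intron_index is not None else '.'}\n"
            )
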