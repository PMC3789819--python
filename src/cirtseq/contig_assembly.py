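"""Contig assembly and contig-level analyses.

Intronic read footprints are clustered into contigs by single linkage: two
footprints merge when the gap between them is at most 500 bp (the scale of
two back-to-back paired-end fragments).  The contig is the unit of
cytoplasmic-retention evidence; this module also provides the length
null-model test, pA-tract contigs, six-frame ORF/stop screens, positional
analyses, the whole-cell length cutoff and the repeat filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from cirtseq.annotation import IntronRecord, reverse_complement
from cirtseq.read_classification import ReadAlignment

Interval = tuple[int, int]

GAP_THRESHOLD = 500
SOMA_MAX_CONTIG_LEN = 400

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class Contig:
    """A gap-clustered island of intronic read footprints within one intron."""

    gene_id: str
    intron_index: int
    chrom: str
    interval: Interval
    n_fragments: int
    has_exon_junction_end: bool = False

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def name(self) -> str:
        return f"{self.gene_id}|i{self.intron_index}|{self.interval[0]}-{self.interval[1]}"


@dataclass
class PATractContig:
    """A cluster of internal adenosine tracts (gap-clustered, strict <500 bp)."""

    intron: IntronRecord
    interval: Interval  # positions on the sense-strand intron sequence

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class OrfScreen:
    """Six-frame ORF / stop-codon screen of a contig sequence."""

    orf_aa_per_frame: list[int]  # frames: +0,+1,+2,-0,-1,-2
    stop_per_frame: list[bool]
    max_orf_aa: int = field(init=False)
    has_stop_all_six_frames: bool = field(init=False)

    def __post_init__(self) -> None:
        self.max_orf_aa = max(self.orf_aa_per_frame)
        self.has_stop_all_six_frames = all(self.stop_per_frame)


# ---------------------------------------------------------------------------
# assembly


def _footprint(frag: ReadAlignment, clip: Interval | None) -> Interval | None:
    s, e = frag.footprint
    if clip is not None:
        s, e = max(s, clip[0]), min(e, clip[1])
        if e <= s:
            return None
    return (s, e)


def assemble_contigs(
    fragments: Sequence[ReadAlignment],
    gap_threshold: int = GAP_THRESHOLD,
    *,
    gene_id: str = "",
    intron_index: int = 0,
    intron_interval: Interval | None = None,
    chrom: str = "",
    junction_fragments: Sequence[ReadAlignment] = (),
) -> list[Contig]:
    """Single-linkage clustering of intronic fragment footprints.

    Adjacent footprints merge iff the gap between them is <= ``gap_threshold``
    ("separated by no more than 500 bp").  Contig intervals are clipped to
    the intron when ``intron_interval`` is given; exon-intron junction
    fragments never extend a contig but set ``has_exon_junction_end`` when
    they overlap or abut a contig end.
    """
    feet = []
    for frag in fragments:
        fp = _footprint(frag, intron_interval)
        if fp is not None:
            feet.append(fp)
    if not feet:
        return []
    feet.sort()
    clusters: list[list[int]] = [[feet[0][0], feet[0][1], 1]]
    for s, e in feet[1:]:
        cur = clusters[-1]
        if s - cur[1] <= gap_threshold:
            cur[1] = max(cur[1], e)
            cur[2] += 1
        else:
            clusters.append([s, e, 1])
    jfeet = [jf.footprint for jf in junction_fragments]
    contigs = []
    for s, e, n in clusters:
        has_j = any(js <= e and je >= s for js, je in jfeet)  # overlap or abut
        contigs.append(
            Contig(
                gene_id=gene_id,
                intron_index=intron_index,
                chrom=chrom,
                interval=(s, e),
                n_fragments=n,
                has_exon_junction_end=has_j,
            )
        )
    return contigs


# ---------------------------------------------------------------------------
# length null model


def length_null_test(lengths: Sequence[int | float]) -> tuple[float, float]:
    """Kolmogorov–Smirnov test of contig lengths against an exponential null.

    Random starts and ends of sequenced intervals would give exponentially
    distributed lengths; the rate is estimated as 1/mean(lengths), which
    makes the nominal p-value conservative (the null is rejected less often
    than alpha).  Returns ``(D, p)``.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 8:
        raise ValueError("need at least 8 lengths")
    mean = lengths.mean()
    if mean <= 0:
        raise ValueError("lengths must be positive")
    d, p = stats.kstest(lengths, "expon", args=(0, mean))
    return float(d), float(p)


# ---------------------------------------------------------------------------
# pA tract contigs


def find_pa_tracts(sense_seq: str, min_len: int = 9) -> list[Interval]:
    """Maximal pure-A runs of at least ``min_len`` nt on the sense strand."""
    tracts = []
    i, n = 0, len(sense_seq)
    while i < n:
        if sense_seq[i] == "A":
            j = i
            while j < n and sense_seq[j] == "A":
                j += 1
            if j - i >= min_len:
                tracts.append((i, j))
            i = j
        else:
            i += 1
    return tracts


def pa_tract_contigs(
    intron: IntronRecord, sense_seq: str, min_len: int = 9, gap: int = GAP_THRESHOLD
) -> list[PATractContig]:
    """Cluster internal pA tracts >= ``min_len`` separated by strictly less
    than ``gap`` bp into tract contigs (coordinates on the sense sequence)."""
    tracts = find_pa_tracts(sense_seq, min_len=min_len)
    if not tracts:
        return []
    clusters = [list(tracts[0])]
    for s, e in tracts[1:]:
        if s - clusters[-1][1] < gap:
            clusters[-1][1] = e
        else:
            clusters.append([s, e])
    return [PATractContig(intron=intron, interval=(s, e)) for s, e in clusters]


# ---------------------------------------------------------------------------
# ORF / stop screen


def _frame_orf_and_stop(seq: str, offset: int) -> tuple[int, bool]:
    """Longest ATG-initiated ORF (aa, stop excluded; open 3' end counts) and
    stop presence in one reading frame.  Codons containing N are neither
    start nor stop."""
    best = 0
    cur = -1  # -1: not in ORF; else aa count so far
    has_stop = False
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            has_stop = True
            if cur > best:
                best = cur
            cur = -1
        elif cur >= 0:
            cur += 1
        elif codon == "ATG":
            cur = 1
    if cur > best:
        best = cur
    return best, has_stop


def orf_screen(seq: str) -> OrfScreen:
    """Maximal ORF length and stop-codon presence in all six frames
    (three sense, three antisense)."""
    seq = seq.upper()
    rc = reverse_complement(seq)
    orfs, stops = [], []
    for strand_seq in (seq, rc):
        for offset in range(3):
            aa, stop = _frame_orf_and_stop(strand_seq, offset)
            orfs.append(aa)
            stops.append(stop)
    return OrfScreen(orf_aa_per_frame=orfs, stop_per_frame=stops)


# ---------------------------------------------------------------------------
# positional analyses


def contig_position_thirds(contig: Contig, intron: IntronRecord) -> int:
    """Which third of the intron (1 = 5'-most on the transcribed strand) the
    contig starts in.  Thirds are half-open with boundaries at floor(L/3)
    and floor(2L/3); assignment is by the contig's 5' start."""
    istart, iend = intron.interval
    if intron.strand == "+":
        pos = contig.interval[0] - istart
    else:
        pos = iend - contig.interval[1]
    length = intron.length
    if pos < length // 3:
        return 1
    if pos < (2 * length) // 3:
        return 2
    return 3


def halves_analysis(
    genes: Iterable[tuple[int, Sequence[int]]],
) -> dict[str, float]:
    """Pooled 5'/3'-half proportions of retained introns for genes with >= 5
    introns.

    Each item is ``(n_introns, retained_intron_indices)``.  A retained
    intron goes to the 5' half when its index <= floor(n/2) and to the 3'
    half when its index > ceil(n/2); the odd middle intron is excluded.
    Fractions are over the pooled counted introns.
    """
    n5 = n3 = 0
    for n_introns, retained in genes:
        if n_introns < 5:
            continue
        half = n_introns // 2
        for idx in retained:
            if idx <= half:
                n5 += 1
            elif n_introns % 2 == 1 and idx == (n_introns + 1) // 2:
                continue  # odd middle intron
            else:
                n3 += 1
    total = n5 + n3
    return {
        "n_5prime": n5,
        "n_3prime": n3,
        "fraction_5prime": n5 / total if total else math.nan,
        "fraction_3prime": n3 / total if total else math.nan,
    }


# ---------------------------------------------------------------------------
# filters on contigs


def apply_length_cutoff(
    contigs: Iterable[Contig], max_len: int = SOMA_MAX_CONTIG_LEN
) -> list[Contig]:
    """Whole-cell (soma/tissue-derived single cell) mode: keep contigs with
    length <= ``max_len`` nt to minimize hnRNA contamination."""
    return [c for c in contigs if c.length <= max_len]


def repeat_overlap_filter(
    contigs: Sequence[Contig], repeats: Sequence[tuple[str, int, int]] | None
) -> tuple[list[Contig], list[Contig]]:
    """Split contigs into (overlapping, clean) against repeat intervals.

    A single shared base makes a contig "overlapping"; half-open adjacency
    does not.  With no repeat annotation the filter is skipped and all
    contigs are clean.
    """
    if not repeats:
        return [], list(contigs)
    by_chrom: dict[str, list[Interval]] = {}
    for chrom, s, e in repeats:
        by_chrom.setdefault(chrom, []).append((s, e))
    for ivs in by_chrom.values():
        ivs.sort()
    overlapping, clean = [], []
    for c in contigs:
        cs, ce = c.interval
        hit = any(s < ce and cs < e for s, e in by_chrom.get(c.chrom, ()))
        (overlapping if hit else clean).append(c)
    return overlapping, clean


def write_contigs_bed(contigs: Iterable[Contig], path) -> None:
    """Contigs as BED6+ (score = supporting fragments, extra columns:
    length, junction-end flag)."""
    with open(path, "w") as out:
        for c in contigs:
            s, e = c.interval
            out.write(
                f"{c.chrom}\t{s}\t{e}\t{c.name}\t{c.n_fragments}\t.\t"
                f"{c.length}\t{int(c.has_exon_junction_end)}\n"
            )
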