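"""Gene models, introns, and per-intron sequence features.

All internal coordinates are 0-based half-open genomic intervals on the
reference strand.  GTF input (1-based inclusive) is converted at the
boundary.  Intron indices count 5'->3' in transcription order, so for
minus-strand genes intron 1 is the rightmost gap in genome coordinates.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Raised for malformed annotation records."""


@dataclass
class GeneModel:
    """One transcript model: ordered, non-overlapping exons on one chromosome.

    ``gene_id`` identifies the model; in the default per-transcript mode it
    is the transcript identifier.  ``exons`` are 0-based half-open intervals
    sorted by start.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: at least one exon required")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if e <= s:
                raise AnnotationError(f"{self.gene_id}: empty exon [{s},{e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class IntronRecord:
    """Per-intron metadata.

    ``intron_index`` is 1-based, numbered from the 5' end of the transcript.
    ``max_internal_pa_tract`` is the longest sense-strand adenosine
    homopolymer of at least ``min_pa_len`` nucleotides (0 when none reaches
    the threshold); it is left at -1 until sequence features are computed.
    """

    gene_id: str
    intron_index: int
    chrom: str
    strand: str
    interval: Interval
    gc_fraction: float = math.nan
    max_internal_pa_tract: int = -1

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def name(self) -> str:
        return f"{self.gene_id}|i{self.intron_index}"


class GenomeSequence:
    """Chromosome name -> uppercase nucleotide string over {A,C,G,T,N}.

    Wraps either an in-memory mapping or a ``pyfaidx.Fasta`` handle behind
    one slicing interface.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = seqs

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        from pyfaidx import Fasta

        return cls(_FaidxView(Fasta(str(path), sequence_always_upper=True)))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._seqs[chrom][start:end]).upper()

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])


class _FaidxView:
    def __init__(self, fasta):
        self._fasta = fasta

    def __contains__(self, chrom):
        return chrom in self._fasta

    def __getitem__(self, chrom):
        return self._fasta[chrom]


# ---------------------------------------------------------------------------
# loading


def load_gene_models(
    path: str | Path,
    *,
    fmt: str | None = None,
    genome: GenomeSequence | None = None,
    strict: bool = False,
) -> list[GeneModel]:
    """Load transcript models from a BED12 or GTF file.

    One :class:`GeneModel` is produced per transcript (BED12 line / GTF
    transcript_id).  Overlapping transcripts of a gene are analyzed
    separately; downstream reporting rolls calls up per gene id.  With a
    ``genome``, models on unknown chromosomes are skipped with a warning
    (or raise in ``strict`` mode).
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    if fmt == "bed":
        models = list(_read_bed12(path))
    elif fmt == "gtf":
        models = list(_read_gtf(path))
    else:
        raise ValueError(f"unknown annotation format: {fmt}")

    if genome is not None:
        kept = []
        for m in models:
            if m.chrom not in genome:
                msg = f"{m.gene_id}: unknown chromosome {m.chrom!r}"
                if strict:
                    raise AnnotationError(msg)
                log.warning("%s — skipped", msg)
                continue
            kept.append(m)
        models = kept
    return models


def _read_bed12(path: Path) -> Iterable[GeneModel]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(f)}")
            try:
                chrom, start = f[0], int(f[1])
                name, strand = f[3], f[5]
                nblocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != nblocks or len(offsets) != nblocks:
                raise AnnotationError(f"{path}:{lineno}: blockCount mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            yield GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf(path: Path) -> Iterable[GeneModel]:
    """Group GTF exon features by transcript_id; 1-based inclusive -> half-open."""
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise AnnotationError(f"{path}:{lineno}: GTF needs 9 fields")
            if f[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            tid = attrs.get("transcript_id")
            if tid is None:
                raise AnnotationError(f"{path}:{lineno}: exon lacks transcript_id")
            try:
                start, end = int(f[3]) - 1, int(f[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            rec = transcripts.get(tid)
            if rec is None:
                rec = transcripts[tid] = {"chrom": f[0], "strand": f[6], "exons": []}
                order.append(tid)
            rec["exons"].append((start, end))
    for tid in order:
        rec = transcripts[tid]
        yield GeneModel(gene_id=tid, chrom=rec["chrom"], strand=rec["strand"], exons=rec["exons"])


# ---------------------------------------------------------------------------
# introns


def derive_introns(model: GeneModel) -> list[IntronRecord]:
    """Introns are the gaps between consecutive exons, indexed 5'->3'.

    A plus-strand gene's intron 1 is the leftmost gap; on the minus strand
    indexing runs right to left.  Zero-length gaps (book-ended exons) are
    skipped.
    """
    gaps = [
        (e0, s1)
        for (_, e0), (s1, _) in zip(model.exons, model.exons[1:])
        if s1 > e0
    ]
    if model.strand == "-":
        gaps = gaps[::-1]
    return [
        IntronRecord(
            gene_id=model.gene_id,
            intron_index=i,
            chrom=model.chrom,
            strand=model.strand,
            interval=g,
        )
        for i, g in enumerate(gaps, start=1)
    ]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _longest_run(seq: str, base: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c == base else 0
        if run > best:
            best = run
    return best


def gc_fraction(seq: str) -> float:
    """GC fraction with N excluded from numerator and denominator; NaN if all N."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return math.nan
    return (seq.count("G") + seq.count("C")) / acgt


def intron_sequence_features(
    intron: IntronRecord, genome: GenomeSequence, min_pa_len: int = 10
) -> IntronRecord:
    """Fill in GC fraction and the maximal internal pA tract.

    The pA tract is the longest pure adenosine run on the transcribed
    (sense) strand: A-runs on the reference for plus-strand genes, T-runs
    for minus-strand genes.  Runs shorter than ``min_pa_len`` are treated
    as no tract (0), matching the convention used for background matching.
    """
    seq = genome.fetch(intron.chrom, *intron.interval)
    intron.gc_fraction = gc_fraction(seq)
    run = _longest_run(seq, "A" if intron.strand == "+" else "T")
    intron.max_internal_pa_tract = run if run >= min_pa_len else 0
    return intron


def intron_sense_sequence(intron: IntronRecord, genome: GenomeSequence) -> str:
    """Intron sequence read 5'->3' on the transcribed strand."""
    seq = genome.fetch(intron.chrom, *intron.interval)
    return seq if intron.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# writers


def write_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as out:
        for m in models:
            start, end = m.span
            sizes = ",".join(str(e - s) for s, e in m.exons)
            offsets = ",".join(str(s - start) for s, _ in m.exons)
            out.write(
                "\t".join(
                    [
                        m.chrom,
                        str(start),
                        str(end),
                        m.gene_id,
                        "0",
                        m.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(m.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def write_introns_bed6(introns: Iterable[IntronRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for it in introns:
            s, e = it.interval
            out.write(f"{it.chrom}\t{s}\t{e}\t{it.name}\t0\t{it.strand}\n")
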