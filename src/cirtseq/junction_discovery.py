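"""Intron-internal splice junction discovery.

De-novo junction callers report every junction crossed by spliced reads.
A junction whose donor and acceptor both lie strictly inside one annotated
intron implies processing within that intron — the splice-level signature
of retained-sequence biogenesis.  Quality gates: a known splice signal,
at least one uniquely mapping crossing read, and >= 8 bp aligned on each
side of the junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cirtseq.annotation import GenomeSequence, IntronRecord

# canonical GT-AG plus known non-canonical GC-AG / AT-AC, and their
# reverse complements (the protocol is unstranded)
ACCEPTED_SIGNALS = frozenset(
    {"GT-AG", "GC-AG", "AT-AC", "CT-AC", "CT-GC", "GT-AT"}
)

MIN_OVERHANG = 8


@dataclass
class JunctionCall:
    """An accepted intron-internal junction with its quality evidence."""

    chrom: str
    donor: int
    acceptor: int
    splice_signal: str
    n_unique_reads: int
    max_overhang_each_side: int
    host_gene_id: str
    host_intron_index: int

    @property
    def spliced_length(self) -> int:
        return self.acceptor - self.donor


def read_junction_table(path: str | Path) -> pd.DataFrame:
    """Raw de-novo junction calls: chrom, start, end, signal, unique_reads,
    overhang_left, overhang_right (TSV with header)."""
    return pd.read_csv(path, sep="\t")


def call_intron_intron_junctions(
    raw: pd.DataFrame,
    introns_by_gene: Mapping[str, Sequence[IntronRecord]],
    accepted_signals: frozenset[str] = ACCEPTED_SIGNALS,
    min_overhang: int = MIN_OVERHANG,
    min_unique_reads: int = 1,
) -> tuple[list[JunctionCall], int]:
    """Filter raw junctions down to high-quality intron-internal calls.

    A junction is accepted when its splice signal is in the accepted set,
    it is crossed by >= ``min_unique_reads`` uniquely mapping reads with
    >= ``min_overhang`` bp on each side, and both ends fall strictly inside
    one annotated intron of one gene.  Junctions touching annotated exon
    boundaries are ordinary splicing; they are excluded and counted.
    Returns ``(calls, n_exonic_boundary)``.
    """
    flat = [
        it for introns in introns_by_gene.values() for it in introns
    ]
    by_chrom: dict[str, list[IntronRecord]] = {}
    for it in flat:
        by_chrom.setdefault(it.chrom, []).append(it)

    calls: list[JunctionCall] = []
    n_boundary = 0
    for row in raw.itertuples(index=False):
        donor, acceptor = int(row.start), int(row.end)
        if acceptor <= donor:
            continue
        if row.signal not in accepted_signals:
            continue
        if int(row.unique_reads) < min_unique_reads:
            continue
        overhang = min(int(row.overhang_left), int(row.overhang_right))
        if overhang < min_overhang:
            continue
        host = None
        inside_gene = False
        for it in by_chrom.get(row.chrom, ()):
            s, e = it.interval
            if s < donor and acceptor < e:
                host = it
                break
            if s < acceptor and donor < e:
                inside_gene = True  # overlaps intron but crosses a boundary
        if host is None:
            if inside_gene:
                n_boundary += 1
            continue
        calls.append(
            JunctionCall(
                chrom=row.chrom,
                donor=donor,
                acceptor=acceptor,
                splice_signal=row.signal,
                n_unique_reads=int(row.unique_reads),
                max_overhang_each_side=overhang,
                host_gene_id=host.gene_id,
                host_intron_index=host.intron_index,
            )
        )
    return calls, n_boundary


def _low_complexity_flank(
    genome: GenomeSequence, chrom: str, pos: int, flank: int = 50, max_run: int = 10
) -> bool:
    """True when a homopolymer run >= ``max_run`` lies within ``flank`` nt of
    ``pos`` — a proxy for sequence unsuitable for specific primer design."""
    start = max(0, pos - flank)
    seq = genome.fetch(chrom, start, pos + flank)
    run, prev = 0, ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        if run >= max_run:
            return True
    return False


def junction_selection_criteria(
    calls: Sequence[JunctionCall],
    expression: Mapping[str, float],
    intron_lengths: Mapping[tuple[str, int], int],
    genome: GenomeSequence | None = None,
    max_intron_len: int = 20_000,
    min_spliced: int = 100,
) -> list[JunctionCall]:
    """Select junctions suitable for targeted (PCR) validation.

    Criteria: host-intron length < ``max_intron_len``; spliced-out length
    >= ``min_spliced``; host-gene expression above the sample median; and,
    when a genome is given, no low-complexity (homopolymer >= 10) stretch
    within 50 nt of either junction side.
    """
    if expression:
        median_expr = float(np.median(list(expression.values())))
    else:
        median_expr = 0.0
    selected = []
    for c in calls:
        if intron_lengths.get((c.host_gene_id, c.host_intron_index), 0) >= max_intron_len:
            continue
        if c.spliced_length < min_spliced:
            continue
        if expression.get(c.host_gene_id, 0.0) <= median_expr:
            continue
        if genome is not None and (
            _low_complexity_flank(genome, c.chrom, c.donor)
            or _low_complexity_flank(genome, c.chrom, c.acceptor)
        ):
            continue
        selected.append(c)
    return selected


def write_junctions_tsv(calls: Iterable[JunctionCall], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write(
            "chrom\tdonor\tacceptor\tsignal\tunique_reads\toverhang\t"
            "gene_id\tintron_index\tspliced_length\n"
        )
        for c in calls:
            out.write(
                f"{c.chrom}\t{c.donor}\t{c.acceptor}\t{c.splice_signal}\t"
                f"{c.n_unique_reads}\t{c.max_overhang_each_side}\t"
                f"{c.host_gene_id}\t{c.host_intron_index}\t{c.spliced_length}\n"
            )
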