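"""Seeded synthetic genomes, annotations, and aligned fragments with planted
ground-truth CIRTs.

The generator emulates the structure of subcellular RNA-seq data: expressed
genes with exonic fragment coverage, a subset of genes carrying a single
retained intron whose intronic reads concentrate in a short (~360 nt)
segment, optional full-intron hnRNA contamination (whole-cell/tissue
samples), intergenic noise kept clear of annotated loci, internal pA
tracts, intron-internal splice junctions, and annotation decoys (ncRNA,
poly(A) site, predicted gene, antisense) overlapping known introns.
Fragments are emitted as already-aligned footprints — the pipeline's
contract starts at alignments, so no sequencing-error or aligner model is
involved.  Everything is drawn from one seeded generator, so the same seed
reproduces the same dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cirtseq.annotation import (
    GeneModel,
    GenomeSequence,
    IntronRecord,
    derive_introns,
    intron_sequence_features,
    write_bed12,
)
from cirtseq.read_classification import ReadAlignment

DECOY_CLASSES = ("ncRNA", "polyA_site", "predicted_gene", "antisense")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Depths are mean fold-coverages; a paired fragment covers two
    ``read_length`` mates.  ``hnRNA_rate`` is the full-intron coverage of
    unspliced precursors: 0 for dissected dendrites, positive for
    whole-cell (soma/tissue) samples.
    """

    seed: int
    structure_seed: int | None = None  # shared genome/annotation across replicates
    n_genes: int = 200
    n_chroms: int = 4
    introns_per_gene: tuple[int, int] = (2, 10)  # uniform inclusive
    exon_len_range: tuple[int, int] = (100, 250)
    intron_len_median: float = 1300.0  # lognormal median of rodent introns
    intron_len_sigma: float = 0.8
    intron_len_max: int = 20_000
    intergenic_gap: int = 3000
    read_length: int = 50
    frag_span_range: tuple[int, int] = (120, 300)
    cirt_gene_fraction: float = 0.5
    retained_introns_per_cirt_gene: int = 1
    segment_len_mean: float = 360.0
    segment_len_sd: float = 60.0
    exonic_depth: float = 20.0
    intronic_depth: float = 20.0
    hnRNA_rate: float = 0.0
    intergenic_depth: float = 0.02
    pa_tract_fraction: float = 0.47  # introns given an internal pA tract
    pa_tract_len_range: tuple[int, int] = (10, 14)
    junction_end_fraction: float = 0.3  # segments abutting an exon boundary
    n_junction_only_introns: int = 5
    n_planted_junctions: int = 10
    n_decoy_junctions: int = 6
    n_decoys_per_class: int = 5
    classifier_pad: int = 1000  # keep intergenic noise beyond this flank

    def __post_init__(self) -> None:
        for name in (
            "cirt_gene_fraction",
            "pa_tract_fraction",
            "junction_end_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("exonic_depth", "intronic_depth", "hnRNA_rate", "intergenic_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class IntronTruth:
    retained: bool = False
    segment: tuple[int, int] | None = None
    pa_tract_len: int = 0
    decoy_flags: list[str] = field(default_factory=list)
    junction_only: bool = False


@dataclass
class TruthTable:
    """Machine-readable ground truth, consistent with the emitted reads."""

    cirt_genes: set[str]
    introns: dict[tuple[str, int], IntronTruth]
    junctions: list[dict]

    def retained_keys(self) -> set[tuple[str, int]]:
        return {k for k, v in self.introns.items() if v.retained}

    def clean_retained_keys(self) -> set[tuple[str, int]]:
        return {
            k
            for k, v in self.introns.items()
            if v.retained and not v.decoy_flags and not v.junction_only
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "cirt_genes": sorted(self.cirt_genes),
                "introns": [
                    {"gene_id": g, "intron_index": i, **asdict(t)}
                    for (g, i), t in sorted(self.introns.items())
                ],
                "junctions": self.junctions,
            },
            indent=1,
        )


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeSequence
    models: list[GeneModel]
    introns_by_gene: dict[str, list[IntronRecord]]
    fragments: list[ReadAlignment]
    decoys: dict[str, list]
    junction_table: pd.DataFrame
    truth: TruthTable
    chrom_lengths: dict[str, int]


# ---------------------------------------------------------------------------


def _sample_spans(rng, lo, hi, n):
    return rng.integers(lo, hi + 1, size=n)


def _project_to_genome(exons, tx_start, tx_end):
    """Map a transcript-coordinate interval to genomic blocks through exons."""
    blocks = []
    offset = 0
    for s, e in exons:
        elen = e - s
        lo = max(tx_start, offset)
        hi = min(tx_end, offset + elen)
        if hi > lo:
            blocks.append((s + lo - offset, s + hi - offset))
        offset += elen
    return blocks


def _paired_blocks(start: int, span: int, read_len: int):
    """Footprint blocks of a paired fragment: two mates, or one block when
    the span leaves no inner gap."""
    if span <= 2 * read_len + 5:
        return [(start, start + span)]
    return [(start, start + read_len), (start + span - read_len, start + span)]


def simulate(config: SimConfig) -> SimResult:
    """Generate one synthetic sample; deterministic given ``config.seed``.

    Structural draws (gene layout, genome sequence, pA tracts) come from
    ``structure_seed`` (default: the sample seed), so replicate samples can
    share one genome and annotation while reads and retention differ.
    """
    struct_seed = config.structure_seed if config.structure_seed is not None else config.seed
    rng_struct = np.random.default_rng(struct_seed)
    rng = np.random.default_rng(config.seed)
    read_len = config.read_length

    # --- gene structures --------------------------------------------------
    genes_per_chrom = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    models: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    gi = 0
    for ci, n_on_chrom in enumerate(genes_per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = config.intergenic_gap
        for _ in range(n_on_chrom):
            gi += 1
            n_introns = int(
                rng_struct.integers(config.introns_per_gene[0], config.introns_per_gene[1] + 1)
            )
            exon_lens = _sample_spans(
                rng_struct, config.exon_len_range[0], config.exon_len_range[1], n_introns + 1
            )
            mu = np.log(config.intron_len_median)
            intron_lens = np.minimum(
                rng_struct.lognormal(mu, config.intron_len_sigma, size=n_introns).astype(int)
                + 2 * read_len,
                config.intron_len_max,
            )
            exons = []
            pos = cursor
            for k, elen in enumerate(exon_lens):
                exons.append((pos, pos + int(elen)))
                pos += int(elen)
                if k < n_introns:
                    pos += int(intron_lens[k])
            strand = "+" if rng_struct.random() < 0.5 else "-"
            models.append(
                GeneModel(gene_id=f"G{gi:04d}", chrom=chrom, strand=strand, exons=exons)
            )
            cursor = pos + config.intergenic_gap
        chrom_lengths[chrom] = cursor

    introns_by_gene = {m.gene_id: derive_introns(m) for m in models}
    model_by_id = {m.gene_id: m for m in models}

    # --- genome sequence with structurally planted pA tracts --------------
    seq_arrays = {
        chrom: _BASES[rng_struct.integers(0, 4, size=length)].copy()
        for chrom, length in chrom_lengths.items()
    }

    def plant_pa(chrom: str, strand: str, lo: int, hi: int, length: int) -> None:
        if hi - lo <= length + 2:
            return
        start = int(rng_struct.integers(lo + 1, hi - length - 1))
        base = b"A" if strand == "+" else b"T"
        seq_arrays[chrom][start : start + length] = np.frombuffer(base, dtype="S1")

    for m in models:
        for it in introns_by_gene[m.gene_id]:
            if rng_struct.random() < config.pa_tract_fraction:
                length = int(
                    rng_struct.integers(
                        config.pa_tract_len_range[0], config.pa_tract_len_range[1] + 1
                    )
                )
                plant_pa(m.chrom, m.strand, *it.interval, length)

    genome = GenomeSequence(
        {chrom: arr.tobytes().decode("ascii") for chrom, arr in seq_arrays.items()}
    )
    for gid, introns in introns_by_gene.items():
        for it in introns:
            intron_sequence_features(it, genome)

    # --- choose CIRT genes and retained segments --------------------------
    n_cirt = int(round(config.cirt_gene_fraction * config.n_genes))
    order = rng.permutation(len(models))
    cirt_ids = [models[i].gene_id for i in order[:n_cirt]]
    truth_introns: dict[tuple[str, int], IntronTruth] = {
        (m.gene_id, it.intron_index): IntronTruth()
        for m in models
        for it in introns_by_gene[m.gene_id]
    }

    segments: dict[tuple[str, int], tuple[int, int, str | None]] = {}
    for gid in cirt_ids:
        introns = introns_by_gene[gid]
        n_ret = min(config.retained_introns_per_cirt_gene, len(introns))
        picks = rng.choice(len(introns), size=n_ret, replace=False)
        for pk in picks:
            it = introns[int(pk)]
            ilen = it.length
            seg_len = 0
            for _ in range(20):
                seg_len = int(rng.normal(config.segment_len_mean, config.segment_len_sd))
                if read_len < seg_len <= ilen:
                    break
            else:
                seg_len = min(max(seg_len, read_len + 1), ilen)
            seg_len = min(seg_len, ilen)
            s0, e0 = it.interval
            abut = None
            if seg_len >= ilen - 2:
                # fills the intron: necessarily abuts the 5' boundary
                abut = "left"
                seg = (s0, s0 + seg_len)
            elif rng.random() < config.junction_end_fraction:
                # segment abuts the exon boundary at one intron end
                abut = "left" if rng.random() < 0.5 else "right"
                seg = (s0, s0 + seg_len) if abut == "left" else (e0 - seg_len, e0)
            else:
                lo, hi = s0 + 1, e0 - seg_len - 1
                start = int(rng.integers(lo, max(lo + 1, hi)))
                seg = (start, start + seg_len)
            segments[(gid, it.intron_index)] = (seg[0], seg[1], abut)
            truth_introns[(gid, it.intron_index)] = IntronTruth(
                retained=True, segment=(seg[0], seg[1])
            )

    # --- junction-only decoy introns (no internal reads) ------------------
    non_cirt = [m.gene_id for m in models if m.gene_id not in set(cirt_ids)]
    junction_only_keys: list[tuple[str, int]] = []
    for gid in non_cirt[: config.n_junction_only_introns]:
        introns = introns_by_gene[gid]
        it = introns[int(rng.integers(len(introns)))]
        junction_only_keys.append((gid, it.intron_index))
        truth_introns[(gid, it.intron_index)].junction_only = True

    # record per-intron pA truth from the final sequence so truth is exact
    for gid, introns in introns_by_gene.items():
        for it in introns:
            truth_introns[(gid, it.intron_index)].pa_tract_len = it.max_internal_pa_tract

    # --- fragments --------------------------------------------------------
    fragments: list[ReadAlignment] = []
    fid = 0

    def n_frags(depth: float, length: int) -> int:
        return int(round(depth * length / (2 * read_len)))

    def add_fragment(chrom: str, blocks) -> None:
        nonlocal fid
        fid += 1
        fragments.append(
            ReadAlignment(fragment_id=f"f{fid:07d}", chrom=chrom, blocks=blocks)
        )

    span_lo, span_hi = config.frag_span_range
    for m in models:
        mrna_len = sum(e - s for s, e in m.exons)
        for _ in range(n_frags(config.exonic_depth, mrna_len)):
            span = int(rng.integers(span_lo, span_hi + 1))
            span = min(span, mrna_len)
            t0 = int(rng.integers(0, max(1, mrna_len - span + 1)))
            tx_blocks = []
            if span <= 2 * read_len + 5:
                tx_blocks = [(t0, t0 + span)]
            else:
                tx_blocks = [(t0, t0 + read_len), (t0 + span - read_len, t0 + span)]
            blocks = []
            for ts, te in tx_blocks:
                blocks.extend(_project_to_genome(m.exons, ts, te))
            add_fragment(m.chrom, blocks)

    for (gid, idx), (s, e, abut) in sorted(segments.items()):
        m = model_by_id[gid]
        seg_len = e - s
        for _ in range(max(1, n_frags(config.intronic_depth, seg_len))):
            span = min(int(rng.integers(span_lo, span_hi + 1)), seg_len)
            start = int(rng.integers(s, e - span + 1))
            add_fragment(m.chrom, _paired_blocks(start, span, read_len))
        if abut is not None:
            boundary = s if abut == "left" else e
            for _ in range(max(2, n_frags(config.intronic_depth, seg_len) // 8)):
                half = read_len // 2
                j_block = (boundary - half, boundary + half)
                if abut == "left":
                    mate = (min(s + 60, e - read_len), min(s + 60, e - read_len) + read_len)
                else:
                    mate = (max(e - 60 - read_len, s), max(e - 60 - read_len, s) + read_len)
                add_fragment(m.chrom, sorted([j_block, mate]))

    for gid, idx in junction_only_keys:
        m = model_by_id[gid]
        it = next(i for i in introns_by_gene[gid] if i.intron_index == idx)
        s0, e0 = it.interval
        half = read_len // 2
        for _ in range(3):
            add_fragment(m.chrom, [(s0 - half, s0 + half)])

    if config.hnRNA_rate > 0:
        for m in models:
            for it in introns_by_gene[m.gene_id]:
                for _ in range(n_frags(config.hnRNA_rate, it.length)):
                    span = min(int(rng.integers(span_lo, span_hi + 1)), it.length)
                    start = int(rng.integers(it.interval[0], it.interval[1] - span + 1))
                    add_fragment(m.chrom, _paired_blocks(start, span, read_len))

    # intergenic noise, kept clear of gene spans plus the classifier pad
    intergenic_zones = []
    for chrom, length in chrom_lengths.items():
        spans = sorted(m.span for m in models if m.chrom == chrom)
        prev = 0
        margin = config.classifier_pad + 100
        for s, e in spans:
            if s - margin - span_hi > prev + margin:
                intergenic_zones.append((chrom, prev + margin, s - margin - span_hi))
            prev = e
        if length - span_hi > prev + margin:
            intergenic_zones.append((chrom, prev + margin, length - span_hi))
    total_zone = sum(e - s for _, s, e in intergenic_zones)
    if intergenic_zones and config.intergenic_depth > 0:
        weights = np.array([e - s for _, s, e in intergenic_zones], dtype=float)
        weights /= weights.sum()
        for _ in range(n_frags(config.intergenic_depth, total_zone)):
            zi = int(rng.choice(len(intergenic_zones), p=weights))
            chrom, zs, ze = intergenic_zones[zi]
            span = int(rng.integers(span_lo, span_hi + 1))
            start = int(rng.integers(zs, ze - span + 1)) if ze - span > zs else zs
            add_fragment(chrom, _paired_blocks(start, span, read_len))

    # --- decoys -----------------------------------------------------------
    decoys: dict[str, list] = {cls: [] for cls in DECOY_CLASSES}
    ret_keys = sorted(segments)
    rng.shuffle(ret_keys)
    cursor = 0
    for cls in DECOY_CLASSES:
        take = ret_keys[cursor : cursor + config.n_decoys_per_class]
        cursor += config.n_decoys_per_class
        for gid, idx in take:
            m = model_by_id[gid]
            it = next(i for i in introns_by_gene[gid] if i.intron_index == idx)
            s, e, _ = segments[(gid, idx)]
            if cls == "polyA_site":
                pos = int(rng.integers(it.interval[0], it.interval[1]))
                decoys[cls].append((m.chrom, pos))
            elif cls == "predicted_gene":
                # overlaps the intron (single-base rule is at intron level)
                decoys[cls].append((m.chrom, it.interval[0], it.interval[0] + 200))
            else:
                # ncRNA / antisense must overlap a contig: hit the segment
                mid = (s + e) // 2
                decoys[cls].append((m.chrom, mid - 40, mid + 40))
            truth_introns[(gid, idx)].decoy_flags.append(cls)

    # --- junction table ---------------------------------------------------
    junction_rows = []
    truth_junctions = []
    candidates = sorted(segments)
    rng.shuffle(candidates)
    n_good = 0
    for gid, idx in candidates:
        if n_good >= config.n_planted_junctions:
            break
        m = model_by_id[gid]
        it = next(i for i in introns_by_gene[gid] if i.intron_index == idx)
        s0, e0 = it.interval
        if e0 - s0 < 400:
            continue
        donor = int(rng.integers(s0 + 20, s0 + (e0 - s0) // 2))
        max_len = e0 - donor - 20
        spliced = int(rng.integers(120, min(max_len, 2000) + 1)) if max_len > 120 else max_len
        acceptor = donor + spliced
        junction_rows.append(
            dict(
                chrom=m.chrom,
                start=donor,
                end=acceptor,
                signal="GT-AG",
                unique_reads=int(rng.integers(1, 5)),
                overhang_left=int(rng.integers(8, 20)),
                overhang_right=int(rng.integers(8, 20)),
            )
        )
        truth_junctions.append(
            dict(chrom=m.chrom, donor=donor, acceptor=acceptor,
                 gene_id=gid, intron_index=idx, quality="good")
        )
        n_good += 1
    # decoy junctions: bad overhang, bad signal, exon-boundary crossers
    for j in range(config.n_decoy_junctions):
        gid, idx = candidates[j % len(candidates)] if candidates else (None, None)
        if gid is None:
            break
        m = model_by_id[gid]
        it = next(i for i in introns_by_gene[gid] if i.intron_index == idx)
        s0, e0 = it.interval
        kind = ("bad_overhang", "bad_signal", "exon_crossing")[j % 3]
        donor = s0 + 30
        acceptor = min(donor + 150, e0 - 10)
        signal, oleft = "GT-AG", 12
        if kind == "bad_overhang":
            oleft = 7
        elif kind == "bad_signal":
            signal = "AA-TT"
        else:
            donor, acceptor = s0 - 40, s0 + 120  # crosses the exon boundary
        junction_rows.append(
            dict(chrom=m.chrom, start=donor, end=acceptor, signal=signal,
                 unique_reads=1, overhang_left=oleft, overhang_right=12)
        )
        truth_junctions.append(
            dict(chrom=m.chrom, donor=donor, acceptor=acceptor,
                 gene_id=gid, intron_index=idx, quality=kind)
        )

    junction_table = pd.DataFrame(
        junction_rows,
        columns=["chrom", "start", "end", "signal", "unique_reads",
                 "overhang_left", "overhang_right"],
    )

    truth = TruthTable(
        cirt_genes=set(cirt_ids), introns=truth_introns, junctions=truth_junctions
    )
    return SimResult(
        config=config,
        genome=genome,
        models=models,
        introns_by_gene=introns_by_gene,
        fragments=fragments,
        decoys=decoys,
        junction_table=junction_table,
        truth=truth,
        chrom_lengths=chrom_lengths,
    )


# ---------------------------------------------------------------------------
# writers


def emit_decoys(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate under ``config`` and write only the decoy annotation BEDs
    (one per class, each overlapping a disjoint known subset of planted
    introns)."""
    result = simulate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for cls, items in result.decoys.items():
        p = outdir / f"decoy_{cls}.bed"
        with open(p, "w") as out:
            for item in items:
                if cls == "polyA_site":
                    chrom, pos = item
                    out.write(f"{chrom}\t{pos}\t{pos + 1}\t{cls}\n")
                else:
                    chrom, s, e = item
                    out.write(f"{chrom}\t{s}\t{e}\t{cls}\n")
        paths[cls] = p
    return paths


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write all simulated artifacts in standard text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    fa = outdir / "genome.fa"
    with open(fa, "w") as out:
        for chrom, length in result.chrom_lengths.items():
            out.write(f">{chrom}\n")
            seq = result.genome.fetch(chrom, 0, length)
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")
    paths["genome"] = fa

    bed = outdir / "genes.bed"
    write_bed12(result.models, bed)
    paths["annotation"] = bed

    frag = outdir / "fragments.bed"
    with open(frag, "w") as out:
        for f in result.fragments:
            s, e = f.footprint
            sizes = ",".join(str(be - bs) for bs, be in f.blocks)
            offsets = ",".join(str(bs - s) for bs, _ in f.blocks)
            out.write(
                f"{f.chrom}\t{s}\t{e}\t{f.fragment_id}\t{int(f.unique)}\t.\t"
                f"{s}\t{e}\t0\t{len(f.blocks)}\t{sizes}\t{offsets}\n"
            )
    paths["fragments"] = frag

    for cls, items in result.decoys.items():
        p = outdir / f"decoy_{cls}.bed"
        with open(p, "w") as out:
            for item in items:
                if cls == "polyA_site":
                    chrom, pos = item
                    out.write(f"{chrom}\t{pos}\t{pos + 1}\t{cls}\n")
                else:
                    chrom, s, e = item
                    out.write(f"{chrom}\t{s}\t{e}\t{cls}\n")
        paths[cls] = p

    jt = outdir / "junctions.tsv"
    result.junction_table.to_csv(jt, sep="\t", index=False)
    paths["junctions"] = jt

    tt = outdir / "truth.json"
    tt.write_text(result.truth.to_json())
    paths["truth"] = tt
    return paths
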