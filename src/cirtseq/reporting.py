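"""Summary statistics and tables.

Per-gene roll-ups of read evidence and passed retention calls, replicate
overlaps, the confident shared-intron set, read-count threshold sweeps,
exon/intron density correlation, intron-position frequencies, and EST
overlap classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cirtseq.annotation import GeneModel
from cirtseq.cirt_filters import RetainedIntronCall
from cirtseq.contig_assembly import Contig
from cirtseq.read_classification import FragmentAssignment

Interval = tuple[int, int]

GENE_CATEGORIES = ("exonic_only", "exonic_and_intronic", "intron_only", "none")


@dataclass
class GeneCirtSummary:
    gene_id: str
    category: str
    n_retained_introns: int
    n_introns: int
    max_intron_fragments: int
    intron_exon_density_ratio: float = math.nan


@dataclass
class OverlapReport:
    sample_a: str
    sample_b: str
    gene_overlap: float
    gene_jaccard: float
    intron_overlap: float
    intron_jaccard: float


def summarize_genes(
    assignments: Sequence[FragmentAssignment],
    passed_calls: Sequence[RetainedIntronCall],
    models: Mapping[str, GeneModel],
) -> list[GeneCirtSummary]:
    """Per-gene category roll-up.

    A gene is counted ("Total Genes") when it has >= 1 unique fragment of
    any category; "expressed" means >= 1 exonic fragment.  Categories:
    exonic reads with / without a passed retained-intron call, and
    intron-only genes whose only evidence is a passed intronic call.
    """
    exonic_genes = {
        a.gene_id for a in assignments if a.category == "exonic" and a.gene_id
    }
    any_read_genes = {a.gene_id for a in assignments if a.gene_id}
    calls_by_gene: dict[str, list[RetainedIntronCall]] = {}
    for c in passed_calls:
        calls_by_gene.setdefault(c.gene_id, []).append(c)

    out = []
    for gene_id in sorted(any_read_genes):
        calls = calls_by_gene.get(gene_id, [])
        has_exonic = gene_id in exonic_genes
        if has_exonic and calls:
            cat = "exonic_and_intronic"
        elif has_exonic:
            cat = "exonic_only"
        elif calls:
            cat = "intron_only"
        else:
            cat = "none"
        out.append(
            GeneCirtSummary(
                gene_id=gene_id,
                category=cat,
                n_retained_introns=len(calls),
                n_introns=models[gene_id].n_introns if gene_id in models else 0,
                max_intron_fragments=max(
                    (c.total_intronic_fragments for c in calls), default=0
                ),
            )
        )
    return out


def gene_summary_table(summaries: Sequence[GeneCirtSummary]) -> pd.DataFrame:
    """Prevalence table: counts and percentages per category, with
    percentages over total genes with any read evidence."""
    total = len(summaries)
    counts = {cat: 0 for cat in GENE_CATEGORIES}
    for s in summaries:
        counts[s.category] += 1
    n_intronic = counts["exonic_and_intronic"] + counts["intron_only"]
    rows = [
        ("total_genes", total, 100.0),
        ("genes_with_exonic_reads", counts["exonic_only"] + counts["exonic_and_intronic"], math.nan),
        ("exonic_and_intronic", counts["exonic_and_intronic"], math.nan),
        ("intron_only", counts["intron_only"], math.nan),
        ("total_with_intronic", n_intronic, math.nan),
    ]
    df = pd.DataFrame(rows, columns=["class", "n_genes", "pct"])
    if total:
        df["pct"] = 100.0 * df["n_genes"] / total
    return df


def replicate_overlap(
    calls_a: Sequence[RetainedIntronCall],
    calls_b: Sequence[RetainedIntronCall],
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapReport:
    """Gene- and intron-level overlap between two samples' passed calls.

    The headline overlap uses the min-set denominator
    (|intersection| / min(|A|, |B|)); the Jaccard form (union denominator)
    is also reported.  Intron overlap is conditioned on shared genes and
    computed over (gene, intron_index) pairs.
    """
    genes_a = {c.gene_id for c in calls_a}
    genes_b = {c.gene_id for c in calls_b}
    shared_genes = genes_a & genes_b

    def _frac(inter: int, na: int, nb: int, jaccard: bool) -> float:
        denom = (na + nb - inter) if jaccard else min(na, nb)
        return inter / denom if denom else 0.0

    gi = len(shared_genes)
    pairs_a = {c.key for c in calls_a if c.gene_id in shared_genes}
    pairs_b = {c.key for c in calls_b if c.gene_id in shared_genes}
    pi = len(pairs_a & pairs_b)
    return OverlapReport(
        sample_a=name_a,
        sample_b=name_b,
        gene_overlap=_frac(gi, len(genes_a), len(genes_b), False),
        gene_jaccard=_frac(gi, len(genes_a), len(genes_b), True),
        intron_overlap=_frac(pi, len(pairs_a), len(pairs_b), False),
        intron_jaccard=_frac(pi, len(pairs_a), len(pairs_b), True),
    )


def shared_intron_set(
    samples: Mapping[str, Sequence[RetainedIntronCall]],
) -> list[tuple[str, int]]:
    """(gene, intron_index) pairs passed in every sample — the most
    confident retention set."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    sets = [
        {c.key for c in calls} for calls in samples.values()
    ]
    return sorted(set.intersection(*sets))


def threshold_sweep(
    calls: Sequence[RetainedIntronCall],
    n_total_genes: int,
    cutoffs: Sequence[int] = (1, 32, 256),
) -> pd.DataFrame:
    """Fraction of genes with >= cutoff supporting fragments in at least
    one passed retained intron, for each read-count cutoff; also lists the
    genes surviving the highest cutoff (e.g. for GO export)."""
    best: dict[str, int] = {}
    for c in calls:
        best[c.gene_id] = max(best.get(c.gene_id, 0), c.total_intronic_fragments)
    rows = []
    for cut in cutoffs:
        n = sum(1 for v in best.values() if v >= cut)
        rows.append((cut, n, n / n_total_genes if n_total_genes else 0.0))
    return pd.DataFrame(rows, columns=["cutoff", "n_genes", "fraction"])


def high_count_gene_list(
    calls: Sequence[RetainedIntronCall], cutoff: int = 256
) -> list[str]:
    """Genes with >= ``cutoff`` fragments in some passed intron, ranked by
    their maximal intronic fragment count (descending)."""
    best: dict[str, int] = {}
    for c in calls:
        best[c.gene_id] = max(best.get(c.gene_id, 0), c.total_intronic_fragments)
    return [g for g, v in sorted(best.items(), key=lambda kv: (-kv[1], kv[0])) if v >= cutoff]


def intron_exon_density_ratio(
    assignments: Sequence[FragmentAssignment],
    passed_calls: Sequence[RetainedIntronCall],
    models: Mapping[str, GeneModel],
) -> dict[str, float]:
    """Per-gene ratio of intronic to exonic per-base read density.

    Intronic density counts fragments in passed retained introns over those
    introns' total length; exonic density counts exonic fragments over the
    exon-union length.  Genes without exonic reads get NaN.
    """
    exonic_counts: dict[str, int] = {}
    for a in assignments:
        if a.category == "exonic" and a.gene_id:
            exonic_counts[a.gene_id] = exonic_counts.get(a.gene_id, 0) + 1
    by_gene: dict[str, list[RetainedIntronCall]] = {}
    for c in passed_calls:
        by_gene.setdefault(c.gene_id, []).append(c)
    ratios: dict[str, float] = {}
    for gene_id, calls in by_gene.items():
        model = models.get(gene_id)
        if model is None:
            continue
        exon_nt = sum(e - s for s, e in model.exons)
        intron_nt = sum(c.intron_interval[1] - c.intron_interval[0] for c in calls)
        intron_frags = sum(c.total_intronic_fragments for c in calls)
        n_exonic = exonic_counts.get(gene_id, 0)
        if n_exonic == 0 or intron_nt == 0:
            ratios[gene_id] = math.nan
            continue
        ratios[gene_id] = (intron_frags / intron_nt) / (n_exonic / exon_nt)
    return ratios


def density_correlation(
    exon_density: Sequence[float],
    intron_density: Sequence[float],
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between per-gene exonic and intronic read densities.

    Returns (r, two-sided p); NaN for degenerate input (n < 3 or a
    constant vector).
    """
    x = np.asarray(exon_density, dtype=float)
    y = np.asarray(intron_density, dtype=float)
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method: {method}")
    return float(r.statistic), float(r.pvalue)


def intron_position_frequency(
    calls: Sequence[RetainedIntronCall],
    models: Mapping[str, GeneModel],
    n_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Frequency of retained introns along the normalized 5'->3' gene model.

    Each passed call maps to position (index - 0.5) / n_introns in (0, 1)
    (a single-intron gene sits at 0.5).  Returns (bin_edges, frequencies,
    chi-square uniformity p-value).
    """
    positions = []
    for c in calls:
        n = models[c.gene_id].n_introns
        if n <= 0:
            continue
        positions.append((c.intron_index - 0.5) / n)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(positions, bins=edges)
    total = counts.sum()
    freqs = counts / total if total else counts.astype(float)
    p = stats.chisquare(counts).pvalue if total else math.nan
    return edges, freqs, float(p)


def est_overlap(
    contigs: Sequence[Contig], ests: Sequence[tuple[str, int, int]]
) -> dict[str, int]:
    """Classify each contig against EST alignments.

    Classes (precedence contained > containing > partial): contig fully
    within an EST; an EST properly within the contig; any other staggered
    overlap.  Contigs with no EST overlap are uncounted.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for chrom, s, e in ests:
        by_chrom.setdefault(chrom, []).append((s, e))
    counts = {"contig_within_est": 0, "est_within_contig": 0, "partial": 0}
    for c in contigs:
        cs, ce = c.interval
        hits = [(s, e) for s, e in by_chrom.get(c.chrom, ()) if s < ce and cs < e]
        if not hits:
            continue
        if any(s <= cs and ce <= e for s, e in hits):
            counts["contig_within_est"] += 1
        elif any(cs <= s and e <= ce and (cs < s or e < ce) for s, e in hits):
            counts["est_within_contig"] += 1
        else:
            counts["partial"] += 1
    return counts
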