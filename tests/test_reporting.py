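"""Per-gene summaries, overlaps, sweeps, correlations, EST classes."""

import math

import numpy as np
import pytest

from cirtseq.annotation import GeneModel
from cirtseq.cirt_filters import RetainedIntronCall
from cirtseq.contig_assembly import Contig
from cirtseq.read_classification import FragmentAssignment
from cirtseq.reporting import (
    density_correlation,
    est_overlap,
    gene_summary_table,
    high_count_gene_list,
    intron_position_frequency,
    replicate_overlap,
    shared_intron_set,
    summarize_genes,
    threshold_sweep,
)


def make_call(gene, idx=1, n_frags=10):
    return RetainedIntronCall(
        gene_id=gene, intron_index=idx, chrom="c", intron_interval=(0, 1000),
        contigs=[Contig(gene, idx, "c", (100, 400), n_frags)],
        n_internal_fragments=n_frags, n_junction_fragments=0,
    )


def _model(gene, n_exons=4):
    exons = [(i * 1000, i * 1000 + 100) for i in range(n_exons)]
    return GeneModel(gene_id=gene, chrom="c", strand="+", exons=exons)


class TestSummarizeGenes:
    def _assigns(self):
        return [
            FragmentAssignment("f1", "exonic", gene_id="A"),
            FragmentAssignment("f2", "exonic", gene_id="B"),
            FragmentAssignment("f3", "intronic", gene_id="B", intron_index=1),
            FragmentAssignment("f4", "intronic", gene_id="C", intron_index=2),
        ]

    def test_categories(self):
        models = {g: _model(g) for g in "ABC"}
        calls = [make_call("B"), make_call("C", idx=2)]
        out = {s.gene_id: s.category for s in summarize_genes(self._assigns(), calls, models)}
        assert out == {"A": "exonic_only", "B": "exonic_and_intronic", "C": "intron_only"}

    def test_unpassed_call_does_not_make_cirt_gene(self):
        models = {g: _model(g) for g in "ABC"}
        out = {s.gene_id: s.category for s in summarize_genes(self._assigns(), [], models)}
        assert out["B"] == "exonic_only"
        assert out["C"] == "none"

    def test_known_composition_recovered(self, sim_small, sim_small_result):
        """Gene categories recovered exactly against the generator truth."""
        truth = sim_small.truth
        expected_cirt = {g for g, _ in truth.clean_retained_keys()}
        got = {s.gene_id: s.category for s in sim_small_result.gene_summaries}
        for gene, cat in got.items():
            if gene in expected_cirt:
                assert cat in ("exonic_and_intronic", "intron_only")
            else:
                assert cat in ("exonic_only", "none")

    def test_table_conservation(self, sim_small_result):
        df = gene_summary_table(sim_small_result.gene_summaries).set_index("class")
        assert (
            df.loc["exonic_and_intronic", "n_genes"] + df.loc["intron_only", "n_genes"]
            == df.loc["total_with_intronic", "n_genes"]
        )
        assert (df["pct"].dropna() <= 100.0).all()


class TestReplicateOverlap:
    def test_identical_sets(self):
        calls = [make_call("A"), make_call("B")]
        rep = replicate_overlap(calls, calls)
        assert rep.gene_overlap == 1.0 and rep.intron_overlap == 1.0

    def test_disjoint_sets(self):
        rep = replicate_overlap([make_call("A")], [make_call("B")])
        assert rep.gene_overlap == 0.0

    def test_min_denominator(self):
        a = [make_call(f"G{i}") for i in range(10)]
        b = a + [make_call(f"H{i}") for i in range(10)]
        rep = replicate_overlap(a, b)
        assert rep.gene_overlap == 1.0
        assert rep.gene_jaccard == pytest.approx(0.5)

    def test_empty_sample(self):
        rep = replicate_overlap([], [make_call("A")])
        assert rep.gene_overlap == 0.0


class TestSharedIntronSet:
    def test_pair_in_all_samples_included(self):
        samples = {
            "s1": [make_call("A"), make_call("B")],
            "s2": [make_call("A"), make_call("C")],
            "s3": [make_call("A")],
        }
        assert shared_intron_set(samples) == [("A", 1)]

    def test_pair_missing_in_one_sample_excluded(self):
        samples = {"s1": [make_call("A")], "s2": []}
        assert shared_intron_set(samples) == []

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            shared_intron_set({"s1": []})

    def test_planted_shared_pairs_recovered(self):
        shared = [make_call("X"), make_call("Y", idx=3)]
        samples = {
            "s1": shared + [make_call("P1")],
            "s2": shared + [make_call("P2")],
            "s3": shared + [make_call("P3")],
        }
        assert shared_intron_set(samples) == [("X", 1), ("Y", 3)]


class TestThresholdSweep:
    def test_documented_fractions(self):
        calls = [make_call("A", n_frags=10), make_call("B", n_frags=40),
                 make_call("C", n_frags=300)]
        df = threshold_sweep(calls, n_total_genes=3, cutoffs=[1, 32, 256])
        assert list(df["fraction"]) == pytest.approx([1.0, 2 / 3, 1 / 3])

    def test_cutoff_above_all_counts(self):
        df = threshold_sweep([make_call("A", n_frags=10)], 5, cutoffs=[100])
        assert df["fraction"].iloc[0] == 0.0

    def test_monotone_non_increasing(self, sim_small_result):
        df = threshold_sweep(
            sim_small_result.passed_calls,
            n_total_genes=len(sim_small_result.gene_summaries),
            cutoffs=[1, 2, 4, 8, 16, 32, 64, 128, 256],
        )
        fr = list(df["fraction"])
        assert all(a >= b for a, b in zip(fr, fr[1:]))
        assert all(0.0 <= f <= 1.0 for f in fr)

    def test_high_count_gene_list_ranked(self):
        calls = [make_call("A", n_frags=300), make_call("B", n_frags=500),
                 make_call("C", n_frags=10)]
        assert high_count_gene_list(calls, cutoff=256) == ["B", "A"]


def test_intron_exon_density_ratio():
    from cirtseq.reporting import intron_exon_density_ratio

    model = _model("A", n_exons=2)  # exon nt = 200, intron [100, 1000) = 900 nt
    assigns = [
        FragmentAssignment(f"f{i}", "exonic", gene_id="A") for i in range(4)
    ]
    call = RetainedIntronCall(
        gene_id="A", intron_index=1, chrom="c", intron_interval=(100, 1000),
        contigs=[Contig("A", 1, "c", (200, 500), 9)],
        n_internal_fragments=9, n_junction_fragments=0,
    )
    ratios = intron_exon_density_ratio(assigns, [call], {"A": model})
    assert ratios["A"] == pytest.approx((9 / 900) / (4 / 200))


class TestDensityCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = density_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        r, p = density_correlation([1.0] * 10, np.arange(10.0))
        assert math.isnan(r)

    def test_too_small_undefined(self):
        r, _ = density_correlation([1.0, 2.0], [2.0, 1.0])
        assert math.isnan(r)

    def test_independent_densities_near_zero(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(40):
            r, _ = density_correlation(rng.random(5000), rng.random(5000))
            hits += abs(r) < 0.05
        assert hits >= 38  # |r| < 0.05 in at least 95% of draws

    def test_spearman_available(self):
        x = np.arange(10.0)
        r, _ = density_correlation(x, x**3, method="spearman")
        assert r == pytest.approx(1.0)


class TestIntronPositionFrequency:
    def test_first_intron_only_mass_at_left(self):
        models = {"A": _model("A", n_exons=11)}
        calls = [make_call("A", idx=1)]
        edges, freqs, _ = intron_position_frequency(calls, models)
        assert freqs[0] == 1.0

    def test_single_intron_gene_at_half(self):
        models = {"A": _model("A", n_exons=2)}
        calls = [make_call("A", idx=1)]
        edges, freqs, _ = intron_position_frequency(calls, models)
        assert freqs[5] == 1.0  # (1 - 0.5) / 1 = 0.5 lands in bin [0.5, 0.6)

    def test_uniform_planting_is_flat(self):
        rng = np.random.default_rng(3)
        n = 10  # decile midpoints align with the bins
        models, calls = {}, []
        for i in range(3000):
            g = f"G{i}"
            models[g] = _model(g, n_exons=n + 1)
            calls.append(make_call(g, idx=int(rng.integers(1, n + 1))))
        _, freqs, p = intron_position_frequency(calls, models)
        assert p > 0.001
        assert np.allclose(freqs, 0.1, atol=0.03)


class TestEstOverlap:
    def test_contained_contains_partial(self):
        contigs = [
            Contig("A", 1, "c", (100, 200), 1),   # within EST
            Contig("B", 1, "c", (300, 600), 1),   # contains an EST
            Contig("C", 1, "c", (700, 800), 1),   # staggered
            Contig("D", 1, "c", (5000, 5100), 1), # no overlap
        ]
        ests = [("c", 50, 250), ("c", 350, 450), ("c", 750, 900)]
        counts = est_overlap(contigs, ests)
        assert counts == {"contig_within_est": 1, "est_within_contig": 1, "partial": 1}

    def test_precedence_contained_first(self):
        contigs = [Contig("A", 1, "c", (100, 200), 1)]
        ests = [("c", 100, 200), ("c", 150, 400)]
        counts = est_overlap(contigs, ests)
        assert counts["contig_within_est"] == 1 and counts["partial"] == 0
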