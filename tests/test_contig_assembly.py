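"""Contig assembly, length null test, pA contigs, ORF screen, positions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cirtseq.annotation import GeneModel, derive_introns
from cirtseq.contig_assembly import (
    Contig,
    apply_length_cutoff,
    assemble_contigs,
    contig_position_thirds,
    find_pa_tracts,
    halves_analysis,
    length_null_test,
    orf_screen,
    pa_tract_contigs,
    repeat_overlap_filter,
)
from cirtseq.read_classification import ReadAlignment


def _frags(footprints):
    return [
        ReadAlignment(fragment_id=f"f{i}", chrom="c", blocks=[fp])
        for i, fp in enumerate(footprints)
    ]


def brute_force_merge(footprints, gap):
    """Independent oracle: repeatedly merge any pair of intervals whose gap
    is <= ``gap`` until a fixpoint, regardless of order."""
    intervals = [list(fp) for fp in footprints]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(intervals)), 2):
            a, b = intervals[i], intervals[j]
            gap_ab = max(a[0], b[0]) - min(a[1], b[1])
            if gap_ab <= gap:
                merged = [min(a[0], b[0]), max(a[1], b[1])]
                intervals = [
                    iv for k, iv in enumerate(intervals) if k not in (i, j)
                ] + [merged]
                changed = True
                break
    return sorted(tuple(iv) for iv in intervals)


class TestAssembleContigs:
    def test_documented_merge_case(self):
        contigs = assemble_contigs(_frags([(100, 150), (300, 350), (900, 950)]))
        assert [c.interval for c in contigs] == [(100, 350), (900, 950)]
        assert [c.n_fragments for c in contigs] == [2, 1]

    def test_single_fragment(self):
        (c,) = assemble_contigs(_frags([(100, 150)]))
        assert c.interval == (100, 150) and c.n_fragments == 1

    def test_gap_of_exactly_500_merges(self):
        """Footprints separated by no more than 500 bp cluster together."""
        (c,) = assemble_contigs(_frags([(0, 100), (600, 700)]))
        assert c.interval == (0, 700)
        two = assemble_contigs(_frags([(0, 100), (601, 700)]))
        assert len(two) == 2

    def test_empty_input(self):
        assert assemble_contigs([]) == []

    def test_fragment_counts_conserved(self):
        feet = [(0, 80), (40, 120), (700, 750), (100, 180)]
        contigs = assemble_contigs(_frags(feet))
        assert sum(c.n_fragments for c in contigs) == len(feet)

    def test_zero_gap_gives_connected_components(self):
        contigs = assemble_contigs(_frags([(0, 100), (100, 200), (201, 300)]), gap_threshold=0)
        assert [c.interval for c in contigs] == [(0, 200), (201, 300)]

    def test_infinite_gap_gives_single_contig(self):
        contigs = assemble_contigs(
            _frags([(0, 50), (10_000, 10_050), (99_000, 99_050)]),
            gap_threshold=10**9,
        )
        assert len(contigs) == 1

    def test_clipped_to_intron(self):
        (c,) = assemble_contigs(
            _frags([(90, 160)]), intron_interval=(100, 1000)
        )
        assert c.interval == (100, 160)

    def test_junction_fragment_sets_end_flag(self):
        jf = ReadAlignment(fragment_id="j", chrom="c", blocks=[(75, 125)])
        (c,) = assemble_contigs(
            _frags([(100, 200)]), junction_fragments=[jf]
        )
        assert c.has_exon_junction_end
        (c2,) = assemble_contigs(_frags([(100, 200)]))
        assert not c2.has_exon_junction_end

    @given(
        st.lists(
            st.tuples(st.integers(0, 3000), st.integers(1, 300)),
            min_size=1,
            max_size=6,
        )
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_and_order_invariant(self, raw):
        feet = [(s, s + w) for s, w in raw]
        expected = brute_force_merge(feet, 500)
        for perm in itertools.permutations(feet):
            got = [c.interval for c in assemble_contigs(_frags(perm))]
            assert got == expected
            assert got == sorted(got)


class TestLengthNullTest:
    def test_exponential_lengths_not_rejected_typically(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            length_null_test(rng.exponential(360, size=500))[1] < 0.05
            for _ in range(200)
        )
        # rate estimated from the data makes the test conservative
        assert rejections / 200 <= 0.05

    def test_degenerate_equal_lengths_reject(self):
        _, p = length_null_test([360.0] * 100)
        assert p < 1e-10

    def test_normal_lengths_rejected(self):
        rng = np.random.default_rng(1)
        lengths = np.clip(rng.normal(360, 40, size=1000), 1, None)
        _, p = length_null_test(lengths)
        assert p < 0.01

    def test_requires_min_sample(self):
        with pytest.raises(ValueError):
            length_null_test([100.0] * 5)


class TestPATractContigs:
    def _intron(self):
        model = GeneModel(
            gene_id="G", chrom="c", strand="+", exons=[(0, 10), (5000, 5010)]
        )
        return derive_introns(model)[0]

    def test_below_threshold_no_tract(self):
        assert find_pa_tracts("C" * 100 + "A" * 8 + "C" * 100) == []

    def test_nine_a_run_is_one_tract(self):
        seq = "C" * 50 + "A" * 9 + "C" * 50
        (t,) = pa_tract_contigs(self._intron(), seq)
        assert t.length == 9

    def test_distant_tracts_stay_separate(self):
        seq = "A" * 10 + "C" * 600 + "A" * 10
        tracts = pa_tract_contigs(self._intron(), seq)
        assert len(tracts) == 2

    def test_nearby_tracts_cluster_with_strict_gap(self):
        seq = "A" * 10 + "C" * 499 + "A" * 10
        (t,) = pa_tract_contigs(self._intron(), seq)
        assert t.length == 519
        # gap of exactly 500 does not merge (strictly less than 500)
        seq2 = "A" * 10 + "C" * 500 + "A" * 10
        assert len(pa_tract_contigs(self._intron(), seq2)) == 2


class TestOrfScreen:
    def test_atg_taa_is_one_aa(self):
        screen = orf_screen("ATGTAA")
        assert screen.orf_aa_per_frame[0] == 1
        assert max(screen.orf_aa_per_frame[3:]) == 0  # TTACAT has no ATG

    def test_no_atg_anywhere(self):
        screen = orf_screen("CCTCCTCCTCCG")
        assert screen.max_orf_aa == 0

    def test_open_three_prime_end_counts(self):
        screen = orf_screen("ATGAAACCC")
        assert screen.orf_aa_per_frame[0] == 3

    def test_n_codons_neither_start_nor_stop(self):
        with_n = orf_screen("ATGNNNTAA")
        assert with_n.orf_aa_per_frame[0] == 2  # M + X, stop excluded
        assert not orf_screen("TNA").stop_per_frame[0]

    def test_stop_in_all_six_frames_flag(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        screen = orf_screen(seq)
        by_hand = all(screen.stop_per_frame)
        assert screen.has_stop_all_six_frames == by_hand


class TestPositions:
    def _pair(self, strand):
        model = GeneModel(
            gene_id="G", chrom="c", strand=strand, exons=[(0, 100), (1000, 1100)]
        )
        return derive_introns(model)[0]

    def test_contig_at_intron_start_bin1(self):
        intron = self._pair("+")
        c = Contig("G", 1, "c", (100, 150), 1)
        assert contig_position_thirds(c, intron) == 1

    def test_boundary_at_third_is_bin2(self):
        intron = self._pair("+")  # length 900, thirds at 300, 600
        c = Contig("G", 1, "c", (400, 450), 1)
        assert contig_position_thirds(c, intron) == 2

    def test_minus_strand_right_end_is_bin1(self):
        intron = self._pair("-")
        c = Contig("G", 1, "c", (950, 1000), 1)
        assert contig_position_thirds(c, intron) == 1

    def test_last_third(self):
        intron = self._pair("+")
        c = Contig("G", 1, "c", (900, 950), 1)
        assert contig_position_thirds(c, intron) == 3


class TestHalves:
    def test_five_intron_gene_first_two_are_5prime(self):
        res = halves_analysis([(5, [1, 2])])
        assert res["n_5prime"] == 2 and res["n_3prime"] == 0

    def test_odd_middle_intron_excluded(self):
        res = halves_analysis([(5, [3])])
        assert res["n_5prime"] == 0 and res["n_3prime"] == 0

    def test_six_intron_gene_i4_is_3prime(self):
        res = halves_analysis([(6, [4])])
        assert res["n_3prime"] == 1

    def test_genes_below_five_introns_ignored(self):
        res = halves_analysis([(4, [1, 2, 3, 4])])
        assert res["n_5prime"] + res["n_3prime"] == 0

    def test_uniform_retention_is_balanced(self):
        rng = np.random.default_rng(7)
        genes = []
        for _ in range(2000):
            n = int(rng.integers(5, 11))
            retained = [int(rng.integers(1, n + 1))]
            genes.append((n, retained))
        res = halves_analysis(genes)
        assert res["fraction_5prime"] == pytest.approx(0.5, abs=0.05)


class TestContigFilters:
    def test_length_cutoff_boundary(self):
        keep = Contig("G", 1, "c", (0, 400), 1)
        drop = Contig("G", 1, "c", (0, 401), 1)
        assert apply_length_cutoff([keep, drop]) == [keep]
        assert apply_length_cutoff([]) == []

    def test_repeat_single_base_overlap(self):
        c = Contig("G", 1, "c", (100, 200), 1)
        over, clean = repeat_overlap_filter([c], [("c", 199, 250)])
        assert over == [c] and clean == []

    def test_repeat_half_open_adjacency_is_clean(self):
        c = Contig("G", 1, "c", (100, 200), 1)
        over, clean = repeat_overlap_filter([c], [("c", 200, 250)])
        assert over == [] and clean == [c]

    def test_no_repeat_annotation_all_clean(self):
        c = Contig("G", 1, "c", (100, 200), 1)
        over, clean = repeat_overlap_filter([c], None)
        assert clean == [c]
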