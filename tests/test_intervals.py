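"""Interval algebra, Jaccard/Venn statistics, shuffle null and TSS classes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from chromkit.intervals import (
    BedParseError,
    BoundsError,
    DEFAULT_TSS_BINS,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    UndefinedStatisticError,
    classify_by_tss_distance,
    fold_enrichment,
    fraction_of_regions_overlapped,
    jaccard,
    jaccard_matrix,
    multiway_membership,
    multiway_membership_bp,
    read_bed,
    read_chrom_sizes,
    shuffle,
    sort_merge,
    write_bed,
)
from conftest import base_mask, random_interval_set


def iset(*triples, layout=None):
    return IntervalSet(
        [GenomicInterval(c, s, e) for c, s, e in triples], layout=layout
    )


class TestBedIO:
    def test_reads_bed3_interval(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        s = read_bed(p)
        assert len(s) == 1 and not s.merged_flag
        assert (s.intervals[0].chrom, s.intervals[0].start, s.intervals[0].end) == (
            "chr1", 0, 100,
        )

    def test_empty_interval_is_parse_error_with_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\t5\t5\n")
        with pytest.raises(BedParseError, match="line 2"):
            read_bed(p)

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\tx\t100\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_bed(p)

    def test_reader_does_not_merge_overlaps(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\t50\t150\nchr1\t80\t90\n")
        s = read_bed(p)
        assert len(s) == 3 and not s.merged_flag

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# c\nbrowser full\nchr1\t0\t10\n")
        assert len(read_bed(p)) == 1

    def test_out_of_bounds_under_layout(self, tmp_path, toy_layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t9000\t11000\n")
        with pytest.raises(BoundsError):
            read_bed(p, layout=toy_layout)
        p.write_text("chrX\t0\t10\n")
        with pytest.raises(BoundsError):
            read_bed(p, layout=toy_layout)

    def test_bed6_roundtrip(self, tmp_path):
        p = tmp_path / "a.bed"
        s = IntervalSet([GenomicInterval("chr1", 5, 9, "tss_0", 1.5, "-")])
        write_bed(s, p)
        back = read_bed(p)
        assert back.intervals[0] == s.intervals[0]

    def test_chrom_sizes(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t1000\nchr2\t500\n")
        layout = read_chrom_sizes(p)
        assert layout.sizes == {"chr1": 1000, "chr2": 500}


class TestSortMerge:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([(0, 100), (50, 150)], [(0, 150)]),            # overlap merge
            ([(0, 100), (100, 200)], [(0, 200)]),           # adjacency merge
            ([(0, 10), (20, 30)], [(0, 10), (20, 30)]),     # disjoint kept
        ],
    )
    def test_merge_semantics(self, raw, expected):
        merged = sort_merge(iset(*[("chr1", s, e) for s, e in raw]))
        assert [(iv.start, iv.end) for iv in merged] == expected
        assert merged.merged_flag

    def test_total_bp_matches_per_base_oracle(self, toy_layout):
        rng = np.random.default_rng(0)
        s = random_interval_set(rng, toy_layout, 1000, max_len=200)
        masks = base_mask(s, toy_layout)
        assert sort_merge(s).total_bp() == sum(m.sum() for m in masks.values())

    def test_idempotent(self, toy_layout):
        rng = np.random.default_rng(1)
        s = random_interval_set(rng, toy_layout, 50)
        once = sort_merge(s)
        twice = sort_merge(once)
        assert [(iv.chrom, iv.start, iv.end) for iv in once] == [
            (iv.chrom, iv.start, iv.end) for iv in twice
        ]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 100)),
            min_size=1,
            max_size=30,
        )
    )
    def test_merge_never_increases_total_bp(self, pairs):
        s = iset(*[("chr1", a, a + l) for a, l in pairs])
        raw_bp = sum(len(iv) for iv in s)
        assert sort_merge(s).total_bp() <= raw_bp


class TestJaccard:
    def test_identity_is_one(self):
        a = iset(("chr1", 0, 100))
        assert jaccard(a, a).jaccard == 1.0

    def test_half_overlap(self):
        a = iset(("chr1", 0, 100))
        b = iset(("chr1", 50, 150))
        stats = jaccard(a, b)
        assert stats.intersection_bp == 50
        assert stats.union_bp == 150
        assert stats.jaccard == pytest.approx(50 / 150)

    def test_different_chromosomes_disjoint(self):
        assert jaccard(iset(("chr1", 0, 100)), iset(("chr2", 0, 100))).jaccard == 0.0

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            jaccard(IntervalSet(), IntervalSet())

    def test_symmetry_and_oracle_on_random_sets(self, toy_layout):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = random_interval_set(rng, toy_layout, 20)
            b = random_interval_set(rng, toy_layout, 20)
            ma, mb = base_mask(a, toy_layout), base_mask(b, toy_layout)
            inter = sum((ma[c] & mb[c]).sum() for c in ma)
            uni = sum((ma[c] | mb[c]).sum() for c in ma)
            stats = jaccard(a, b)
            assert stats.intersection_bp == inter
            assert stats.union_bp == uni
            assert stats.jaccard == jaccard(b, a).jaccard

    def test_agrees_with_bedtools(self, tmp_path, toy_layout):
        """Cross-check against bedtools jaccard as an independent oracle."""
        import shutil
        import subprocess

        if shutil.which("bedtools") is None:
            pytest.skip("bedtools not on PATH")
        rng = np.random.default_rng(3)
        a = sort_merge(random_interval_set(rng, toy_layout, 30))
        b = sort_merge(random_interval_set(rng, toy_layout, 30))
        fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(a, fa)
        write_bed(b, fb)
        out = subprocess.run(
            ["bedtools", "jaccard", "-a", str(fa), "-b", str(fb)],
            capture_output=True, text=True, check=True,
        ).stdout.splitlines()
        inter_bp, union_bp, j, _ = out[1].split("\t")
        stats = jaccard(a, b)
        assert stats.intersection_bp == int(inter_bp)
        assert stats.union_bp == int(union_bp)
        # bedtools prints the index rounded to 6 decimals
        assert stats.jaccard == pytest.approx(float(j), abs=1e-6)


class TestJaccardMatrix:
    def test_identical_sets_all_ones(self):
        a = iset(("chr1", 0, 100))
        m = jaccard_matrix({"x": a, "y": a, "z": a})
        assert np.allclose(m.values, 1.0)

    def test_disjoint_and_duplicate(self):
        a = iset(("chr1", 0, 100))
        b = iset(("chr1", 200, 300))
        m = jaccard_matrix({"A": a, "B": b, "C": a})
        assert m.loc["A", "C"] == 1.0
        assert m.loc["A", "B"] == 0.0

    def test_matches_pairwise_calls(self, toy_layout):
        rng = np.random.default_rng(4)
        sets = {f"s{i}": random_interval_set(rng, toy_layout, 15) for i in range(4)}
        m = jaccard_matrix(sets)
        for ni in sets:
            for nj in sets:
                assert m.loc[ni, nj] == pytest.approx(
                    jaccard(sets[ni], sets[nj]).jaccard
                )

    def test_empty_pair_is_nan_with_warning(self):
        a = iset(("chr1", 0, 10))
        with pytest.warns(UserWarning):
            m = jaccard_matrix({"A": a, "B": IntervalSet(), "C": IntervalSet()})
        assert math.isnan(m.loc["B", "C"])
        assert m.loc["A", "B"] == 0.0


class TestMultiwayMembership:
    def test_identical_sets_share_signature(self):
        a = iset(("chr1", 0, 100))
        counts = multiway_membership({"A": a, "B": iset(("chr1", 0, 100))}, unit="A")
        assert counts == {frozenset({"A", "B"}): 1}

    def test_disjoint_sets_exclusive(self):
        a = iset(("chr1", 0, 100))
        b = iset(("chr1", 200, 300))
        assert multiway_membership({"A": a, "B": b}, unit="A") == {
            frozenset({"A"}): 1
        }
        assert multiway_membership({"A": a, "B": b}, unit="B") == {
            frozenset({"B"}): 1
        }

    def test_counts_partition_unit_set(self, toy_layout):
        rng = np.random.default_rng(5)
        sets = {f"s{i}": random_interval_set(rng, toy_layout, 50) for i in range(3)}
        for unit in sets:
            counts = multiway_membership(sets, unit=unit)
            assert sum(counts.values()) == len(sets[unit])

    def test_matches_brute_force_per_interval(self, toy_layout):
        rng = np.random.default_rng(6)
        sets = {f"s{i}": random_interval_set(rng, toy_layout, 50) for i in range(3)}
        masks = {n: base_mask(s, toy_layout) for n, s in sets.items()}
        counts = multiway_membership(sets, unit="s0")
        brute = {}
        for iv in sets["s0"]:
            sig = frozenset(
                n for n, m in masks.items() if m[iv.chrom][iv.start : iv.end].any()
            )
            brute[sig] = brute.get(sig, 0) + 1
        assert counts == brute

    def test_base_pair_venn_matches_per_base_oracle(self, toy_layout):
        rng = np.random.default_rng(7)
        sets = {f"s{i}": random_interval_set(rng, toy_layout, 30) for i in range(3)}
        masks = {n: base_mask(s, toy_layout) for n, s in sets.items()}
        counts = multiway_membership_bp(sets)
        brute = {}
        for chrom, clen in toy_layout.sizes.items():
            for pos in range(clen):
                sig = frozenset(n for n in masks if masks[n][chrom][pos])
                if sig:
                    brute[sig] = brute.get(sig, 0) + 1
        assert counts == brute


class TestShuffle:
    def test_forced_placement(self):
        layout = GenomeLayout(("chr1",), (100,))
        s = iset(("chr1", 0, 100), layout=layout)
        out = shuffle(s, layout, seed=0)
        assert (out.intervals[0].start, out.intervals[0].end) == (0, 100)

    def test_seeded_determinism(self, toy_layout):
        rng = np.random.default_rng(8)
        s = random_interval_set(rng, toy_layout, 40)
        a = shuffle(s, toy_layout, seed=42)
        b = shuffle(s, toy_layout, seed=42)
        assert [(iv.chrom, iv.start) for iv in a] == [
            (iv.chrom, iv.start) for iv in b
        ]

    def test_conserves_count_and_length_multiset(self, toy_layout):
        rng = np.random.default_rng(9)
        s = random_interval_set(rng, toy_layout, 60)
        out = shuffle(s, toy_layout, seed=1)
        assert len(out) == len(s)
        for chrom in toy_layout.chrom_names:
            lens_in = sorted(len(iv) for iv in s if iv.chrom == chrom)
            lens_out = sorted(len(iv) for iv in out if iv.chrom == chrom)
            assert lens_in == lens_out

    def test_interval_longer_than_chromosome(self):
        layout = GenomeLayout(("chr1",), (50,))
        s = iset(("chr1", 0, 40))
        tiny = GenomeLayout(("chr1",), (30,))
        with pytest.raises(BoundsError):
            shuffle(s, tiny, seed=0)

    def test_start_positions_uniform(self):
        """10^4 shuffles of a 1-bp interval on a 1000-bp chromosome."""
        layout = GenomeLayout(("chr1",), (1000,))
        s = iset(("chr1", 0, 1))
        starts = [
            shuffle(s, layout, seed=seed).intervals[0].start
            for seed in range(10_000)
        ]
        counts, _ = np.histogram(starts, bins=20, range=(0, 1000))
        assert chisquare(counts).pvalue > 0.01


class TestFoldEnrichment:
    def test_whole_genome_target_fold_one(self, toy_layout):
        target = iset(
            ("chr1", 0, 10_000), ("chr2", 0, 8_000), layout=toy_layout
        )
        peaks = iset(("chr1", 100, 200), ("chr2", 50, 500), layout=toy_layout)
        res = fold_enrichment(
            peaks, target, toy_layout, n_shuffles=20, seed=0, statistic="overlap_bp"
        )
        assert res.fold == pytest.approx(1.0)
        assert res.empirical_p == pytest.approx(1.0)

    def test_requires_min_shuffles(self, toy_layout):
        peaks = iset(("chr1", 0, 10))
        with pytest.raises(ValueError):
            fold_enrichment(peaks, peaks, toy_layout, n_shuffles=5, seed=0)

    def test_zero_expected_mean_sentinel(self):
        layout = GenomeLayout(("chr1", "chr2"), (1000, 1000))
        peaks = iset(("chr2", 0, 10), layout=layout)
        target = iset(("chr1", 0, 1000), layout=layout)
        res = fold_enrichment(
            peaks, target, layout, n_shuffles=20, seed=0, statistic="overlap_bp"
        )
        assert res.infinite_fold and math.isinf(res.fold)

    def test_null_peaks_fold_near_one(self):
        layout = GenomeLayout(("chr1",), (200_000,))
        target = iset(("chr1", 0, 20_000), layout=layout)
        base = iset(*[("chr1", 0, 300)] * 40, layout=layout)
        folds = [
            fold_enrichment(
                shuffle(base, layout, seed=100 + r),
                target,
                layout,
                n_shuffles=40,
                seed=r,
                statistic="overlap_bp",
            ).fold
            for r in range(15)
        ]
        se = np.std(folds, ddof=1) / np.sqrt(len(folds))
        assert abs(np.mean(folds) - 1.0) < 3 * se + 1e-9


class TestTssClassification:
    def tss(self, *positions, chrom="chr1"):
        return IntervalSet(
            [GenomicInterval(chrom, p, p + 1, strand="+") for p in positions]
        )

    def test_midpoint_at_tss_is_under_1kb(self):
        peaks = iset(("chr1", 4_990, 5_010))
        counts = classify_by_tss_distance(peaks, self.tss(5_000))
        assert counts["<1kb"] == 1 and sum(counts.values()) == 1

    def test_5kb_falls_in_3_10kb_class(self):
        peaks = iset(("chr1", 4_990, 5_010))
        counts = classify_by_tss_distance(
            peaks, self.tss(10_000), bins=(1_000, 3_000, 10_000)
        )
        assert counts["3kb-10kb"] == 1

    def test_empty_tss_errors(self):
        with pytest.raises(ValueError):
            classify_by_tss_distance(iset(("chr1", 0, 10)), IntervalSet())

    def test_counts_match_exhaustive_nearest_anchor(self, toy_layout):
        rng = np.random.default_rng(10)
        peaks = random_interval_set(rng, toy_layout, 500, max_len=100)
        tss_pos = {
            "chr1": sorted(rng.integers(0, 10_000, 7).tolist()),
            "chr2": sorted(rng.integers(0, 8_000, 5).tolist()),
        }
        tss = IntervalSet(
            [
                GenomicInterval(c, int(p), int(p) + 1, strand="+")
                for c, ps in tss_pos.items()
                for p in ps
            ]
        )
        bins = (500, 1_000, 3_000)
        counts = classify_by_tss_distance(peaks, tss, bins=bins)
        brute = {k: 0 for k in counts}
        labels = list(counts)
        for iv in peaks:
            d = min(abs(iv.midpoint - p) for p in tss_pos[iv.chrom])
            k = sum(d >= b for b in bins)
            brute[labels[k]] += 1
        assert counts == brute
        assert sum(counts.values()) == len(peaks)


class TestFractionOfRegionsOverlapped:
    def test_full_cover(self, toy_layout):
        regions = iset(("chr1", 10, 20), ("chr1", 100, 200))
        peaks = iset(("chr1", 0, 10_000))
        assert fraction_of_regions_overlapped(regions, peaks) == (1.0, 2, 2)

    def test_disjoint(self):
        regions = iset(("chr1", 0, 10))
        peaks = iset(("chr1", 100, 200))
        assert fraction_of_regions_overlapped(regions, peaks) == (0.0, 0, 1)

    def test_planted_construction(self):
        """200 regions, exactly 60 planted to intersect the peak set."""
        peaks = iset(("chr1", 50_000, 60_000))
        regions = []
        for i in range(200):
            if i < 60:
                regions.append(GenomicInterval("chr1", 50_000 + i * 100, 50_050 + i * 100))
            else:
                regions.append(GenomicInterval("chr1", 100_000 + i * 100, 100_050 + i * 100))
        frac, n_hit, n_total = fraction_of_regions_overlapped(
            IntervalSet(regions), peaks
        )
        assert (frac, n_hit, n_total) == (0.30, 60, 200)
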