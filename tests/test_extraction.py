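"""Locus enumeration, composition building, intersection and SNP filtering."""

import numpy as np
import pytest

from epiclonal import (
    EpiallelePattern,
    Locus,
    build_composition,
    cpg_universe,
    enumerate_loci,
    filter_snp_overlap,
    intersect_samples,
    pattern_words,
)
from epiclonal.extraction import read_bed_intervals, read_vcf_variants

from conftest import composition, make_read


class TestPatternSpace:
    def test_sixteen_patterns_for_four_cpgs(self):
        words = pattern_words(4)
        assert len(words) == 16
        assert len(set(words)) == 16
        assert words[0] == "0000" and words[-1] == "1111"

    def test_index_is_binary_value(self):
        p = EpiallelePattern.from_word("1011")
        assert p.index == 11
        assert EpiallelePattern.from_index(11).word == "1011"

    def test_inconsistent_index_rejected(self):
        with pytest.raises(ValueError):
            EpiallelePattern(word="1011", index=3)


class TestEnumerateLoci:
    def test_single_read_single_window(self):
        read = make_read("chr1", (10, 20, 30, 40), "1011")
        tallies = enumerate_loci([read], m=4)
        locus = Locus("chr1", (10, 20, 30, 40))
        assert set(tallies) == {locus}
        assert tallies[locus][int("1011", 2)] == 1
        assert tallies[locus].sum() == 1

    def test_read_covering_five_cpgs_feeds_two_windows(self):
        read = make_read("chr1", (10, 20, 30, 40, 50), "10110")
        tallies = enumerate_loci([read], m=4)
        assert set(tallies) == {
            Locus("chr1", (10, 20, 30, 40)),
            Locus("chr1", (20, 30, 40, 50)),
        }
        assert tallies[Locus("chr1", (10, 20, 30, 40))][int("1011", 2)] == 1
        assert tallies[Locus("chr1", (20, 30, 40, 50))][int("0110", 2)] == 1

    def test_first_window_only_mode(self):
        read = make_read("chr1", (10, 20, 30, 40, 50), "10110")
        tallies = enumerate_loci([read], m=4, first_window_only=True)
        assert set(tallies) == {Locus("chr1", (10, 20, 30, 40))}

    def test_gap_in_universe_coverage_splits_runs(self):
        # another read establishes CpG 25 in the universe; the first read has
        # no call there, so its CpGs no longer form one consecutive window
        long_read = make_read("chr1", (10, 20, 30, 40), "1011")
        short_read = make_read("chr1", (25, 30, 40, 50), "0110")
        universe = cpg_universe([long_read, short_read])
        tallies = enumerate_loci([long_read], m=4, universe=universe)
        assert tallies == {}

    def test_identical_reads_accumulate(self):
        reads = [make_read("chr1", (10, 20, 30, 40), "0000") for _ in range(60)]
        tallies = enumerate_loci(reads, m=4)
        assert tallies[Locus("chr1", (10, 20, 30, 40))][0] == 60

    def test_empty_input(self):
        assert enumerate_loci([], m=4) == {}

    def test_conservation_of_contributed_windows(self, rng):
        reads = []
        for _ in range(100):
            start = int(rng.integers(0, 50)) * 10
            n_cpgs = int(rng.integers(4, 8))
            word = "".join(str(b) for b in rng.integers(0, 2, n_cpgs))
            reads.append(make_read("chr1", tuple(start + 10 * i for i in range(n_cpgs)), word))
        universe = cpg_universe(reads)
        positions = universe["chr1"]
        index_of = {p: i for i, p in enumerate(positions)}
        expected = 0
        for read in reads:
            idxs = sorted(index_of[p] for p, _ in read.calls)
            run = 1
            for a, b in zip(idxs, idxs[1:]):
                if b == a + 1:
                    run += 1
                else:
                    expected += max(0, run - 3)
                    run = 1
            expected += max(0, run - 3)
        total = sum(int(t.sum()) for t in enumerate_loci(reads, m=4, universe=universe).values())
        assert total == expected


class TestBuildComposition:
    def test_min_reads_boundary(self):
        locus = Locus("chr1", (10, 20, 30, 40))
        below = {locus: np.array([59] + [0] * 15)}
        at = {locus: np.array([60] + [0] * 15)}
        assert build_composition(below, min_reads=60) == {}
        assert locus in build_composition(at, min_reads=60)

    def test_proportions(self):
        locus = Locus("chr1", (10, 20, 30, 40))
        tally = np.zeros(16, dtype=int)
        tally[0], tally[15] = 30, 30
        comp = build_composition({locus: tally}, min_reads=1)[locus]
        assert comp.raw_count == 60
        assert comp.proportions[0] == pytest.approx(0.5)
        assert comp.proportions[15] == pytest.approx(0.5)

    def test_duplication_scales_counts_not_proportions(self):
        locus = Locus("chr1", (10, 20, 30, 40))
        tally = np.zeros(16, dtype=int)
        tally[3], tally[7] = 40, 20
        single = build_composition({locus: tally}, min_reads=1)[locus]
        tripled = build_composition({locus: tally * 3}, min_reads=1)[locus]
        assert tripled.raw_count == 3 * single.raw_count
        np.testing.assert_allclose(tripled.proportions, single.proportions)


class TestIntersectSamples:
    def test_only_shared_loci_survive(self):
        a = composition({"0000": 1.0}, start=100)
        b1 = composition({"0000": 1.0}, start=200)
        b2 = composition({"1111": 1.0}, start=200)
        c = composition({"0000": 1.0}, start=300)
        pairs = intersect_samples(
            {a.locus: a, b1.locus: b1}, {b2.locus: b2, c.locus: c}
        )
        assert [(p[0].locus.start, p[1].locus.start) for p in pairs] == [(200, 200)]

    def test_disjoint_samples_give_empty_intersection(self):
        a = composition({"0000": 1.0}, start=100)
        b = composition({"0000": 1.0}, start=500)
        assert intersect_samples({a.locus: a}, {b.locus: b}) == []


class TestSnpFilter:
    def _pair(self, start=100):
        c = composition({"0000": 1.0}, start=start)
        return (c, c)

    def test_c_to_t_at_locus_cpg_removes_locus(self):
        pair = self._pair(start=100)  # CpGs at 100,110,120,130 (0-based)
        variants = [("chr1", 111, "C", "T")]  # 1-based = 0-based 110
        assert filter_snp_overlap([pair], variants=variants) == []

    def test_g_to_a_at_dyad_g_removes_locus(self):
        pair = self._pair(start=100)
        variants = [("chr1", 112, "G", "A")]  # G of the dyad at C=110
        assert filter_snp_overlap([pair], variants=variants) == []

    def test_distant_or_other_variants_keep_locus(self):
        pair = self._pair(start=100)
        variants = [("chr1", 631, "A", "G"), ("chr1", 111, "C", "G"), ("chr2", 111, "C", "T")]
        assert filter_snp_overlap([pair], variants=variants) == [pair]

    def test_bed_exclusion_interval(self):
        pair = self._pair(start=100)
        assert filter_snp_overlap([pair], exclusion_intervals=[("chr1", 125, 135)]) == []
        assert filter_snp_overlap([pair], exclusion_intervals=[("chr1", 500, 600)]) == [pair]

    def test_vcf_and_bed_readers(self, tmp_path):
        vcf = tmp_path / "snps.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t111\t.\tC\tT,G\t.\t.\t.\n"
            "badline\n"
        )
        variants = read_vcf_variants(vcf)
        assert ("chr1", 111, "C", "T") in variants
        assert ("chr1", 111, "C", "G") in variants
        bed = tmp_path / "mask.bed"
        bed.write_text("chr1\t100\t200\nchr2\t5\t10\n")
        assert read_bed_intervals(bed) == [("chr1", 100, 200), ("chr2", 5, 10)]
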