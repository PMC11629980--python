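"""Interval engine, coordinate conventions and flat-file I/O."""

import numpy as np
import pytest

from epistates.genome_core import (
    GeneRecord,
    GenomeModel,
    GenomicInterval,
    ParseError,
    StateSegmentation,
    ValidationError,
    find_overlaps,
    flank_tss,
    intersect_bp,
    merge_intervals,
    overlap_length,
    read_chrom_sizes,
    read_gene_table,
    read_intervals,
    total_bp,
    write_chrom_sizes,
    write_gene_table,
    write_intervals,
)

from conftest import brute_force_overlaps, random_intervals


class TestTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 20, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -5, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 0, 10, score=-1.0)
        assert GenomicInterval("chr1", 10, 25).length == 15

    def test_gene_tss_tes_strand(self):
        plus = GeneRecord("g", "chr1", 100, 500, "+")
        minus = GeneRecord("g", "chr1", 100, 500, "-")
        assert (plus.tss, plus.tes) == (100, 500)
        assert (minus.tss, minus.tes) == (500, 100)
        with pytest.raises(ValidationError):
            GeneRecord("g", "chr1", 100, 500, "+", {"brain": -1.0})

    def test_segmentation_rejects_overlap_and_bad_labels(self):
        good = [
            GenomicInterval("chr1", 0, 100, "TssA"),
            GenomicInterval("chr1", 100, 300, "Quies"),
        ]
        StateSegmentation("brain", good)
        with pytest.raises(ValidationError):
            StateSegmentation("brain", [GenomicInterval("chr1", 0, 100, "NotAState")])
        with pytest.raises(ValidationError):
            StateSegmentation(
                "brain",
                [GenomicInterval("chr1", 0, 100, "TssA"), GenomicInterval("chr1", 50, 150, "Quies")],
            )


class TestOverlapLength:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 0, 10), ("chr1", 5, 15), 5),
            (("chr1", 0, 10), ("chr1", 10, 20), 0),  # half-open abutment
            (("chr1", 0, 10), ("chr1", 2, 4), 2),  # containment
            (("chr1", 0, 10), ("chr2", 0, 10), 0),  # different chromosomes
        ],
    )
    def test_examples(self, a, b, expected):
        ia, ib = GenomicInterval(*a), GenomicInterval(*b)
        assert overlap_length(ia, ib) == expected
        assert overlap_length(ib, ia) == expected  # symmetry

    def test_bounded_by_min_length(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b = random_intervals(rng, 2)
            assert overlap_length(a, b) <= min(a.length, b.length)


class TestFindOverlaps:
    def test_one_query_two_of_three_subjects(self):
        q = [GenomicInterval("chr1", 100, 200)]
        s = [
            GenomicInterval("chr1", 150, 160),
            GenomicInterval("chr1", 500, 600),
            GenomicInterval("chr1", 190, 300),
        ]
        assert find_overlaps(q, s) == [(0, 0, 10), (0, 2, 10)]

    def test_disjoint_chromosomes_empty(self):
        assert find_overlaps(
            [GenomicInterval("chr1", 0, 10)], [GenomicInterval("chr2", 0, 10)]
        ) == []

    def test_self_join_of_disjoint_set_gives_self_pairs(self):
        ivs = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(5)]
        assert find_overlaps(ivs, ivs) == [(i, i, 50) for i in range(5)]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            q = random_intervals(rng, int(rng.integers(1, 60)))
            s = random_intervals(rng, int(rng.integers(1, 60)))
            assert sorted(find_overlaps(q, s)) == sorted(brute_force_overlaps(q, s))


class TestMerge:
    def test_merge_and_totals(self):
        ivs = [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 50, 150),
            GenomicInterval("chr1", 150, 200),  # abutting: merges
            GenomicInterval("chr2", 0, 10),
        ]
        merged = merge_intervals(ivs)
        assert [(m.chrom, m.start, m.end) for m in merged] == [
            ("chr1", 0, 200),
            ("chr2", 0, 10),
        ]
        assert total_bp(ivs) == 210

    def test_intersect_bp(self):
        a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        b = [GenomicInterval("chr1", 50, 250)]
        assert intersect_bp(a, b) == 50 + 50


class TestFlankTss:
    def test_plus_strand_symmetric(self, genome):
        g = GeneRecord("g", "chr1", 5_000, 9_000, "+")
        iv = flank_tss(g, 3_000, 3_000, genome)
        assert (iv.start, iv.end) == (2_000, 8_000)

    def test_minus_strand_upstream_extends_right(self, genome):
        g = GeneRecord("g", "chr1", 1_000, 5_000, "-")  # tss at 5000
        iv = flank_tss(g, 1_000, 0, genome)
        assert (iv.start, iv.end) == (5_000, 6_000)

    def test_clipping_at_chrom_start(self, genome):
        g = GeneRecord("g", "chr1", 100, 2_000, "+")
        iv = flank_tss(g, 3_000, 3_000, genome)
        assert (iv.start, iv.end) == (0, 3_100)

    def test_unknown_chromosome_errors(self, genome):
        g = GeneRecord("g", "chrZ", 100, 2_000, "+")
        with pytest.raises(ValidationError):
            flank_tss(g, 100, 100, genome)

    def test_strand_reflection(self, genome):
        """Mirroring the chromosome maps the + window to the - window."""
        L = genome.chrom_sizes["chr1"]
        plus = GeneRecord("g", "chr1", 40_000, 50_000, "+")
        mirrored = GeneRecord("g", "chr1", L - 50_000, L - 40_000, "-")
        up, down = 3_000, 1_500
        a = flank_tss(plus, up, down, genome)
        b = flank_tss(mirrored, up, down, genome)
        assert (b.start, b.end) == (L - a.end, L - a.start)


class TestIO:
    def test_bed_roundtrip_and_parsing(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t10\t20\tTssA\n# comment\nchr2\t0\t5\t.\t3.5\n")
        ivs = read_intervals(p)
        assert ivs[0] == GenomicInterval("chr1", 10, 20, "TssA")
        assert ivs[1].score == 3.5 and ivs[1].label is None
        out = tmp_path / "y.bed"
        write_intervals(ivs, out)
        assert read_intervals(out) == ivs

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_intervals(p) == []

    @pytest.mark.parametrize(
        "content,exc",
        [
            ("chr1\t20\t10\n", ValidationError),  # start >= end
            ("chr1\t5\n", ParseError),  # too few columns
            ("chr1\tten\t20\n", ParseError),  # non-integer
        ],
    )
    def test_malformed_lines_name_the_line(self, tmp_path, content, exc):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t1\n" + content)
        with pytest.raises(exc, match="line 2"):
            read_intervals(p)

    def test_gene_table_roundtrip(self, tmp_path, plus_gene, minus_gene):
        p = tmp_path / "genes.tsv"
        write_gene_table([plus_gene, minus_gene], ["brain", "liver"], p)
        genes, tissues = read_gene_table(p)
        assert tissues == ["brain", "liver"]
        assert genes[0].gene_id == "gA" and genes[0].tpm["brain"] == 5.0
        assert genes[1].strand == "-" and genes[1].tss == 26_000

    def test_chrom_sizes_roundtrip(self, tmp_path, genome):
        p = tmp_path / "g.chrom.sizes"
        write_chrom_sizes(genome, p)
        again = read_chrom_sizes(p)
        assert again.chrom_sizes == genome.chrom_sizes
        assert again.total_length == 180_000
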