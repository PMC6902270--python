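"""Interval algebra, readers/writers and annotation oracles."""

import numpy as np
import pytest

from valleycall.intervals import (
    BedParseError,
    GeneAnnotation,
    GenomicInterval,
    classify_context,
    gap,
    nearest_tss,
    read_annotation,
    read_bed,
    read_bedgraph,
    write_bed,
    write_gff3,
)


def make_gene(gene_id, chrom, start, end, strand, exons=()):
    body = GenomicInterval(chrom, start, end, strand)
    ex = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return GeneAnnotation(gene_id, body, ex)


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)

    def test_length_and_midpoint(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.length == 100 and iv.midpoint == 150


class TestBedIO:
    def test_read_simple_record(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tpk1\n")
        ivs = read_bed(p)
        assert ivs == [GenomicInterval("chr1", 100, 200, ".", "pk1")]

    def test_inverted_coordinates_raise_with_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match="line 2"):
            read_bed(p)

    def test_round_trip_is_lossless(self, tmp_path, rng):
        ivs = [
            GenomicInterval(
                f"chr{rng.integers(1, 3)}",
                int(s := rng.integers(0, 10000)),
                int(s + rng.integers(1, 500)),
                ["+", "-", "."][rng.integers(3)],
                f"pk{i}",
                float(rng.integers(0, 100)),
            )
            for i in range(30)
        ]
        p = tmp_path / "rt.bed"
        write_bed(ivs, p)
        assert read_bed(p) == ivs
        # a second round trip is byte identical
        p2 = tmp_path / "rt2.bed"
        write_bed(read_bed(p), p2)
        assert p.read_bytes() == p2.read_bytes()


class TestBedGraph:
    def test_single_run(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t10\t2.5\n")
        track = read_bedgraph(p)
        assert track.mean_over("chr1", 0, 10) == pytest.approx(2.5)

    def test_overlapping_runs_rejected(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t10\t1\nchr1\t5\t15\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_bedgraph(p)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t10\t-1\n")
        with pytest.raises(ValueError):
            read_bedgraph(p)

    def test_empty_file_gives_empty_track(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("")
        assert read_bedgraph(p).chroms == []


class TestAnnotation:
    def test_bed12_tss_respects_strand(self, tmp_path):
        p = tmp_path / "g.bed"
        lines = []
        for name, strand in (("gplus", "+"), ("gminus", "-")):
            lines.append(
                f"chr1\t1000\t2000\t{name}\t0\t{strand}\t1000\t2000\t0\t2\t100,100\t0,900\n"
            )
        p.write_text("".join(lines))
        genes = read_annotation(p, "bed12")
        assert genes[0].tss_pos == 1000
        assert genes[1].tss_pos == 1999
        assert len(genes[0].exons) == 2

    def test_gff3_round_trip(self, tmp_path):
        genes = [
            make_gene("gA", "chr1", 1000, 3000, "+", [(1000, 1200), (2800, 3000)]),
            make_gene("gB", "chr2", 500, 1500, "-", [(600, 800)]),
        ]
        p = tmp_path / "g.gff3"
        write_gff3(genes, p)
        back = read_annotation(p, "gff3")
        assert [g.gene_id for g in back] == ["gA", "gB"]
        b0 = back[0].body
        assert (b0.chrom, b0.start, b0.end, b0.strand) == ("chr1", 1000, 3000, "+")
        assert [(e.start, e.end) for e in back[1].exons] == [(600, 800)]
        assert back[1].tss_pos == 1499

    def test_strandless_gene_rejected(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("chr1\tx\tgene\t1\t100\t.\t.\t.\tID=g1\n")
        with pytest.raises(BedParseError, match="strand"):
            read_annotation(p, "gff3")


class TestGap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((100, 200), (200, 300), 0),
            ((100, 200), (150, 300), -50),
            ((100, 200), (250, 300), 50),
            ((0, 500), (100, 200), -100),
        ],
    )
    def test_examples(self, a, b, expected):
        ga = GenomicInterval("chr1", *a)
        gb = GenomicInterval("chr1", *b)
        assert gap(ga, gb) == expected
        assert gap(gb, ga) == expected  # symmetry

    def test_cross_chromosome_undefined(self):
        assert gap(GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10)) is None

    def test_matches_base_set_oracle(self, rng):
        for _ in range(300):
            a = GenomicInterval("c", int(s := rng.integers(0, 500)), int(s + rng.integers(1, 100)))
            b = GenomicInterval("c", int(s2 := rng.integers(0, 500)), int(s2 + rng.integers(1, 100)))
            g = gap(a, b)
            shared = set(range(a.start, a.end)) & set(range(b.start, b.end))
            if shared:
                assert g == -len(shared)
            else:
                assert g >= 0
                # g bases strictly between the intervals
                lo, hi = min(a.end, b.end), max(a.start, b.start)
                assert g == hi - lo


class TestNearestTss:
    def test_signed_distance(self):
        genes = [make_gene("g400", "c", 400, 1400, "+"), make_gene("g700", "c", 700, 1700, "+")]
        region = GenomicInterval("c", 400, 600)  # midpoint 500
        assert nearest_tss(region, genes) == ("g400", -100)

    def test_tie_breaks_to_smaller_coordinate(self):
        genes = [make_gene("gB", "c", 600, 1600, "+"), make_gene("gA", "c", 100, 401, "-")]
        region = GenomicInterval("c", 400, 600)  # mid 500; TSSs at 400 and 600
        assert nearest_tss(region, genes)[0] == "gA"

    def test_no_gene_on_chromosome(self):
        genes = [make_gene("g", "chr2", 0, 100, "+")]
        assert nearest_tss(GenomicInterval("chr1", 0, 10), genes) is None

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(200):
            genes = [
                make_gene(f"g{i}", "c", int(s := rng.integers(0, 50_000)), int(s) + 100,
                          "+" if rng.random() < 0.5 else "-")
                for i in range(20)
            ]
            region = GenomicInterval("c", int(s := rng.integers(0, 50_000)), int(s) + int(rng.integers(1, 2000)))
            got = nearest_tss(region, genes)
            mid = region.midpoint
            best = min(genes, key=lambda g: (abs(g.tss_pos - mid), g.tss_pos, g.gene_id))
            assert got == (best.gene_id, best.tss_pos - mid)


class TestClassifyContext:
    def test_promoter_upstream_of_plus_tss(self):
        genes = [make_gene("g", "c", 1000, 3000, "+")]
        region = GenomicInterval("c", 998, 1000)  # midpoint 999, 1 bp upstream
        assert classify_context(region, genes) == "promoter"

    def test_promoter_beats_exon(self):
        genes = [
            make_gene("host", "c", 0, 5000, "+", [(2000, 2600)]),
            make_gene("other", "c", 2500, 6000, "+"),  # promoter window covers 500..3000
        ]
        region = GenomicInterval("c", 2200, 2400)  # mid 2300: host exon & other promoter
        assert classify_context(region, genes) == "promoter"

    def test_partition_and_oracle(self, rng):
        genes = [
            make_gene(
                f"g{i}", "c", int(s := rng.integers(0, 80_000)), int(s) + int(rng.integers(1_000, 5_000)),
                "+" if rng.random() < 0.5 else "-",
                [(int(s) + 100, int(s) + 400)],
            )
            for i in range(15)
        ]
        counts = {"promoter": 0, "exonic": 0, "intronic": 0, "intergenic": 0}
        n = 100
        for _ in range(n):
            region = GenomicInterval("c", int(s := rng.integers(0, 80_000)), int(s) + int(rng.integers(1, 3_000)))
            ctx = classify_context(region, genes)
            counts[ctx] += 1
            mid = region.midpoint
            in_prom = in_ex = in_body = False
            for g in genes:
                t = g.tss_pos
                if g.body.strand == "+":
                    lo, hi = t - 2000, t + 500
                else:
                    lo, hi = t - 499, t + 2001
                in_prom |= lo <= mid < hi
                in_ex |= any(e.start <= mid < e.end for e in g.exons)
                in_body |= g.body.start <= mid < g.body.end
            expected = (
                "promoter" if in_prom
                else "exonic" if in_ex
                else "intronic" if in_body
                else "intergenic"
            )
            assert ctx == expected
        assert sum(counts.values()) == n
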