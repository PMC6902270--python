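"""Valley calling, repressive filtering and condition comparison."""

import numpy as np
import pytest

from valleycall.enhancers import (
    PutativeEnhancer,
    call_enhancers,
    call_valleys,
    compare_conditions,
    context_distribution,
    filter_repressive,
    merge_touching_peaks,
)
from valleycall.intervals import GenomicInterval


def iv(start, end, chrom="c"):
    return GenomicInterval(chrom, start, end)


def valley(start, end, chrom="c", condition=""):
    return PutativeEnhancer(
        iv(start, end, chrom),
        iv(max(0, start - 100), start, chrom),
        iv(end, end + 100, chrom),
        condition=condition,
    )


def random_peaks(rng, n, span=100_000):
    peaks = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        peaks.append(iv(s, s + int(rng.integers(50, 800))))
    return peaks


class TestMerge:
    @pytest.mark.parametrize(
        "peaks,expected",
        [
            ([(100, 200), (150, 250)], [(100, 250)]),
            ([(100, 200), (200, 300)], [(100, 300)]),
            ([(100, 200), (250, 300)], [(100, 200), (250, 300)]),
        ],
    )
    def test_examples(self, peaks, expected):
        got = merge_touching_peaks([iv(*p) for p in peaks])
        assert [(p.start, p.end) for p in got] == expected

    def test_union_of_bases_preserved(self, rng):
        peaks = random_peaks(rng, 60, span=20_000)
        merged = merge_touching_peaks(peaks)
        bases = set()
        for p in peaks:
            bases |= set(range(p.start, p.end))
        merged_bases = set()
        for p in merged:
            merged_bases |= set(range(p.start, p.end))
        assert bases == merged_bases
        # merged peaks are disjoint with positive gaps
        for a, b in zip(merged, merged[1:]):
            assert b.start > a.end


class TestCallValleys:
    def test_simple_valley(self):
        got = call_valleys([iv(0, 100), iv(600, 700)], 3000)
        assert len(got) == 1
        assert (got[0].valley.start, got[0].valley.end) == (100, 600)

    def test_max_gap_boundary_excludes(self):
        assert call_valleys([iv(0, 100), iv(3200, 3300)], 3000) == []
        # inclusive at exactly the cutoff
        got = call_valleys([iv(0, 100), iv(3100, 3200)], 3000)
        assert len(got) == 1

    def test_shared_flank(self):
        got = call_valleys([iv(0, 100), iv(600, 700), iv(1000, 1100)], 3000)
        assert len(got) == 2
        assert got[0].right_flank == got[1].left_flank

    def test_invalid_gap_parameter(self):
        with pytest.raises(ValueError):
            call_valleys([], 0)

    def test_matches_adjacent_pair_oracle(self, rng):
        for _ in range(30):
            merged = merge_touching_peaks(random_peaks(rng, 80))
            got = call_valleys(merged, 3000)
            expected = []
            for a, b in zip(merged, merged[1:]):
                if a.chrom == b.chrom and 0 < b.start - a.end <= 3000:
                    expected.append((a.end, b.start))
            assert [(v.valley.start, v.valley.end) for v in got] == expected


class TestFilterRepressive:
    def test_overlap_removes(self):
        assert filter_repressive([valley(100, 600)], [iv(550, 800)]) == []

    def test_book_ended_retained(self):
        kept = filter_repressive([valley(100, 600)], [iv(600, 800)])
        assert len(kept) == 1

    def test_matches_base_overlap_oracle(self, rng):
        cands = [valley(int(s := rng.integers(0, 20_000)), int(s) + int(rng.integers(100, 2000)))
                 for _ in range(40)]
        me3 = random_peaks(rng, 30, span=20_000)
        kept = filter_repressive(cands, me3)
        me3_bases = set()
        for m in me3:
            me3_bases |= set(range(m.start, m.end))
        expected = [
            c for c in cands
            if not (set(range(c.valley.start, c.valley.end)) & me3_bases)
        ]
        assert kept == expected


class TestMonotonicity:
    def test_larger_gap_never_removes_calls(self, rng):
        merged = merge_touching_peaks(random_peaks(rng, 100))
        small = {(v.valley.start, v.valley.end) for v in call_valleys(merged, 1500)}
        large = {(v.valley.start, v.valley.end) for v in call_valleys(merged, 3000)}
        assert small <= large

    def test_extra_me3_never_adds_calls(self, rng):
        cands = [valley(int(s := rng.integers(0, 50_000)), int(s) + 500) for _ in range(30)]
        me3 = random_peaks(rng, 10, span=50_000)
        base = set(map(id, filter_repressive(cands, me3)))
        more = set(map(id, filter_repressive(cands, me3 + random_peaks(rng, 5, span=50_000))))
        assert more <= base


class TestCompareConditions:
    def test_book_ended_is_common(self):
        comp = compare_conditions([valley(100, 600)], [valley(600, 900)])
        assert comp.counts == {"unique_a": 0, "unique_b": 0, "common": 1}

    def test_separated_are_unique(self):
        comp = compare_conditions([valley(100, 600)], [valley(700, 900)])
        assert comp.counts == {"unique_a": 1, "unique_b": 1, "common": 0}

    def test_chain_collapses_to_one_component(self):
        # a1 - b1 - a2 chain through a shared b valley
        a = [valley(100, 600), valley(900, 1400)]
        b = [valley(500, 1000)]
        comp = compare_conditions(a, b)
        assert comp.counts == {"unique_a": 0, "unique_b": 0, "common": 1}
        assert len(comp.common[0][0]) == 2

    def test_matches_graph_component_oracle(self, rng):
        for _ in range(40):
            a = [valley(int(s := rng.integers(0, 30_000)), int(s) + int(rng.integers(100, 2000)), condition="a")
                 for _ in range(rng.integers(1, 30))]
            b = [valley(int(s := rng.integers(0, 30_000)), int(s) + int(rng.integers(100, 2000)), condition="b")
                 for _ in range(rng.integers(1, 30))]
            comp = compare_conditions(a, b)
            # oracle: exhaustive pairwise gap tests + component count via BFS
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(("a", i) for i in range(len(a)))
            g.add_nodes_from(("b", j) for j in range(len(b)))
            for i, ea in enumerate(a):
                for j, eb in enumerate(b):
                    ga = max(ea.valley.start, eb.valley.start) - min(ea.valley.end, eb.valley.end)
                    if ga <= 0:
                        g.add_edge(("a", i), ("b", j))
            comps = [c for c in nx.connected_components(g) if len(c) > 1 or False]
            mixed = [c for c in nx.connected_components(g)
                     if {n[0] for n in c} == {"a", "b"}]
            assert len(comp.common) == len(mixed)
            proj_a = sum(len(pair[0]) for pair in comp.common)
            proj_b = sum(len(pair[1]) for pair in comp.common)
            assert len(comp.unique_a) + proj_a == len(a)
            assert len(comp.unique_b) + proj_b == len(b)


class TestContextDistribution:
    def test_empty(self):
        assert context_distribution([]) == {
            "promoter": 0, "exonic": 0, "intronic": 0, "intergenic": 0
        }

    def test_counts(self):
        import dataclasses

        vs = [dataclasses.replace(valley(100 + 2000 * i, 600 + 2000 * i), context="intergenic")
              for i in range(3)]
        assert context_distribution(vs)["intergenic"] == 3

    def test_unannotated_raises(self):
        with pytest.raises(ValueError):
            context_distribution([valley(100, 600)])


class TestPlantedPipeline:
    def test_planted_targets_recovered(self, small_truth):
        """On the synthetic genome every call maps to its planted target gene."""
        truth, planted = small_truth
        for cond in ("CNT", "FGF"):
            calls = call_enhancers(
                planted.ac_peaks[cond], planted.me3_peaks[cond], truth.genes,
                condition=cond,
            )
            planted_truth = truth.enhancers_of(cond)
            matched = set()
            for c in calls:
                for i, t in enumerate(planted_truth):
                    g = max(c.valley.start, t.valley.start) - min(c.valley.end, t.valley.end)
                    if c.valley.chrom == t.valley.chrom and g < 0:
                        assert c.gene_id == t.target_gene
                        matched.add(i)
            assert matched == set(range(len(planted_truth)))
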