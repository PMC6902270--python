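"""Bimodal-H3K27ac valley enhancer calling and two-condition comparison.

The operational enhancer definition: after merging touching H3K27ac peaks,
every adjacent same-chromosome peak pair whose inter-peak gap is positive
and at most ``max_inner_gap`` (default 3 kb) defines a candidate valley;
candidates whose valley shares >=1 bp with an H3K27me3 peak of the same
condition are discarded (repressed chromatin), and survivors are annotated
with nearest-TSS gene and genomic context.  Two conditions are compared
with a 0 bp gap rule: valleys that touch or overlap across conditions are
"common", the rest are condition-unique.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .intervals import (
    Context,
    GeneAnnotation,
    GenomicInterval,
    PROMOTER_DOWN,
    PROMOTER_UP,
    classify_context,
    gap,
    nearest_tss,
)

DEFAULT_MAX_INNER_GAP = 3000


@dataclass(frozen=True)
class PutativeEnhancer:
    """A valley between two flanking H3K27ac peaks."""

    valley: GenomicInterval
    left_flank: GenomicInterval
    right_flank: GenomicInterval
    gene_id: str | None = None
    distance_to_tss: int | None = None
    context: Context | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        if self.left_flank.end != self.valley.start or self.valley.end != self.right_flank.start:
            raise ValueError("flanks must abut the valley")

    @property
    def span(self) -> GenomicInterval:
        """Full flank-to-flank span (alternative reporting mode)."""
        return GenomicInterval(
            self.valley.chrom, self.left_flank.start, self.right_flank.end
        )


@dataclass
class ConditionComparison:
    """Unique/common partition of two enhancer sets (0 bp gap rule).

    ``common`` holds one entry per connected overlap component, each a pair
    of tuples (members from a, members from b).
    """

    unique_a: list[PutativeEnhancer]
    unique_b: list[PutativeEnhancer]
    common: list[tuple[tuple[PutativeEnhancer, ...], tuple[PutativeEnhancer, ...]]]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
            "common": len(self.common),
        }


def merge_touching_peaks(peaks: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended peaks; result sorted by (chrom, start)."""
    merged: list[GenomicInterval] = []
    for p in sorted(peaks, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == p.chrom and p.start <= merged[-1].end:
            last = merged[-1]
            if p.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, p.end)
            continue
        merged.append(GenomicInterval(p.chrom, p.start, p.end))
    return merged


def call_valleys(
    ac_peaks: Sequence[GenomicInterval],
    max_inner_gap: int = DEFAULT_MAX_INNER_GAP,
    condition: str = "",
) -> list[PutativeEnhancer]:
    """Candidate valleys between adjacent merged H3K27ac peaks.

    A peak may serve as right flank of one valley and left flank of the
    next.  ``ac_peaks`` must be merged and sorted (see
    :func:`merge_touching_peaks`); raises if ``max_inner_gap <= 0``.
    """
    if max_inner_gap <= 0:
        raise ValueError("max_inner_gap must be positive")
    out: list[PutativeEnhancer] = []
    for left, right in zip(ac_peaks, ac_peaks[1:]):
        if left.chrom != right.chrom:
            continue
        g = right.start - left.end
        if g <= 0:
            raise ValueError("ac_peaks must be merged (touching peaks found)")
        if g <= max_inner_gap:
            out.append(
                PutativeEnhancer(
                    valley=GenomicInterval(left.chrom, left.end, right.start),
                    left_flank=left,
                    right_flank=right,
                    condition=condition,
                )
            )
    return out


def filter_repressive(
    candidates: Sequence[PutativeEnhancer],
    me3_peaks: Sequence[GenomicInterval],
) -> list[PutativeEnhancer]:
    """Drop candidates whose valley overlaps an H3K27me3 peak by >=1 bp.

    Book-ended repressive peaks (0 bp gap) do not disqualify a valley.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in me3_peaks:
        by_chrom.setdefault(m.chrom, []).append(m)
    for ms in by_chrom.values():
        ms.sort(key=lambda m: m.start)
    kept: list[PutativeEnhancer] = []
    for cand in candidates:
        v = cand.valley
        hit = any(
            m.start < v.end and v.start < m.end
            for m in by_chrom.get(v.chrom, ())
        )
        if not hit:
            kept.append(cand)
    return kept


def annotate_enhancers(
    enhancers: Sequence[PutativeEnhancer],
    genes: Sequence[GeneAnnotation],
    promoter_up: int = PROMOTER_UP,
    promoter_down: int = PROMOTER_DOWN,
) -> list[PutativeEnhancer]:
    """Attach nearest-TSS gene, signed distance and genomic context to each valley."""
    out: list[PutativeEnhancer] = []
    for e in enhancers:
        hit = nearest_tss(e.valley, genes)
        ctx = classify_context(e.valley, genes, promoter_up, promoter_down)
        if hit is None:
            out.append(replace(e, gene_id=None, distance_to_tss=None, context=ctx))
        else:
            out.append(
                replace(e, gene_id=hit[0], distance_to_tss=hit[1], context=ctx)
            )
    return out


def call_enhancers(
    ac_peaks: Sequence[GenomicInterval],
    me3_peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneAnnotation] = (),
    max_inner_gap: int = DEFAULT_MAX_INNER_GAP,
    condition: str = "",
) -> list[PutativeEnhancer]:
    """Full pipeline: merge -> valleys -> H3K27me3 exclusion -> annotation."""
    merged = merge_touching_peaks(ac_peaks)
    cands = call_valleys(merged, max_inner_gap, condition)
    kept = filter_repressive(cands, me3_peaks)
    if genes:
        kept = annotate_enhancers(kept, genes)
    return kept


def compare_conditions(
    a: Sequence[PutativeEnhancer], b: Sequence[PutativeEnhancer]
) -> ConditionComparison:
    """Partition two enhancer sets into unique/common under the 0 bp gap rule.

    Valleys in the two conditions are linked when ``gap <= 0`` (overlap or
    book-ended); the many-to-many link graph is collapsed into connected
    components, each counted once as a common element.
    """
    n, m = len(a), len(b)
    parent = list(range(n + m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    # sweep per chromosome to avoid the full quadratic scan
    items: list[tuple[str, int, int, int]] = []
    for i, e in enumerate(a):
        items.append((e.valley.chrom, e.valley.start, e.valley.end, i))
    for j, e in enumerate(b):
        items.append((e.valley.chrom, e.valley.start, e.valley.end, n + j))
    items.sort()
    active: list[tuple[str, int, int, int]] = []
    for it in items:
        chrom, start, end, idx = it
        active = [x for x in active if x[0] == chrom and x[2] >= start]
        for other in active:
            if (other[3] < n) != (idx < n):  # cross-condition only
                union(idx, other[3])
        active.append(it)

    return _collect(a, b, n, m, find)


def _collect(a, b, n, m, find) -> ConditionComparison:
    groups: dict[int, tuple[list, list]] = {}
    for i, e in enumerate(a):
        groups.setdefault(find(i), ([], []))[0].append(e)
    for j, e in enumerate(b):
        groups.setdefault(find(n + j), ([], []))[1].append(e)
    unique_a: list[PutativeEnhancer] = []
    unique_b: list[PutativeEnhancer] = []
    common: list[tuple[tuple[PutativeEnhancer, ...], tuple[PutativeEnhancer, ...]]] = []
    for ga, gb in groups.values():
        if ga and gb:
            common.append((tuple(ga), tuple(gb)))
        elif ga:
            unique_a.extend(ga)
        else:
            unique_b.extend(gb)
    return ConditionComparison(unique_a, unique_b, common)


def context_distribution(
    enhancers: Sequence[PutativeEnhancer],
) -> dict[Context, int]:
    """Counts over {promoter, exonic, intronic, intergenic}; requires annotation."""
    counts: Counter = Counter()
    for e in enhancers:
        if e.context is None:
            raise ValueError("enhancer without context annotation")
        counts[e.context] += 1
    return {
        k: counts.get(k, 0)
        for k in ("promoter", "exonic", "intronic", "intergenic")
    }
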