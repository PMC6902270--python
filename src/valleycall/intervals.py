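"""Genomic interval model, interval algebra and flat-file I/O.

All coordinates are 0-based half-open (BED convention) throughout the
package; GFF3 input is converted from 1-based closed at the parser
boundary.  Three container types live here: :class:`GenomicInterval`
(the atom of all peak/enhancer/annotation work), :class:`GeneAnnotation`
(gene body, strand-aware TSS, exons) and :class:`SignalTrack` (sorted
non-overlapping runs of read density, i.e. an in-memory bedGraph).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

Strand = Literal["+", "-", "."]
Context = Literal["promoter", "exonic", "intronic", "intergenic"]

#: Default promoter window around the TSS, strand-oriented (upstream, downstream).
PROMOTER_UP = 2000
PROMOTER_DOWN = 500


class BedParseError(ValueError):
    """A malformed record in a BED-family file; carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open stranded span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body with strand-aware TSS and exon structure.

    The TSS is the length-1 interval at ``body.start`` for + genes and at
    ``body.end - 1`` for - genes.
    """

    gene_id: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand required to define a TSS")
        ex = sorted(self.exons, key=lambda e: e.start)
        for e in ex:
            if e.start < self.body.start or e.end > self.body.end:
                raise ValueError(f"gene {self.gene_id}: exon outside body")
        for a, b in zip(ex, ex[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def tss(self) -> GenomicInterval:
        pos = self.body.start if self.body.strand == "+" else self.body.end - 1
        return GenomicInterval(self.body.chrom, pos, pos + 1, self.body.strand)

    @property
    def tss_pos(self) -> int:
        return self.body.start if self.body.strand == "+" else self.body.end - 1


class SignalTrack:
    """Per-chromosome sorted, non-overlapping runs of non-negative signal.

    Stored as parallel numpy arrays (starts, ends, values) per chromosome
    plus a prefix integral enabling O(log n) exact windowed means.
    """

    def __init__(self) -> None:
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}

    @classmethod
    def from_runs(
        cls, runs: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            if value < 0:
                raise ValueError(f"negative signal value {value} at {chrom}:{start}")
            if start >= end:
                raise ValueError(f"empty run {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, rs in by_chrom.items():
            rs.sort()
            for (s1, e1, _), (s2, _, _) in zip(rs, rs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping bedGraph runs on {chrom} at {s2} < {e1}"
                    )
            starts = np.array([r[0] for r in rs], dtype=np.int64)
            ends = np.array([r[1] for r in rs], dtype=np.int64)
            values = np.array([r[2] for r in rs], dtype=np.float64)
            track._runs[chrom] = (starts, ends, values)
            track._cum[chrom] = np.concatenate(
                [[0.0], np.cumsum((ends - starts) * values)]
            )
        return track

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (
                np.empty(0, np.int64),
                np.empty(0, np.int64),
                np.empty(0, np.float64),
            ),
        )

    def integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Integral of the track over ``[0, p)`` for each position p (vectorised).

        Positions left of 0 and uncovered bases contribute 0.
        """
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._runs:
            return np.zeros(positions.shape, dtype=np.float64)
        starts, ends, values = self._runs[chrom]
        cum = self._cum[chrom]
        p = np.clip(positions, 0, None)
        i = np.searchsorted(starts, p, side="right")
        j = np.maximum(i - 1, 0)  # last run starting at or before p
        partial = np.clip(p - starts[j], 0, ends[j] - starts[j]) * values[j]
        return np.where(i > 0, cum[j] + partial, 0.0)

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean signal over [start, end); uncovered bases are 0."""
        if end <= start:
            raise ValueError("empty window")
        a, b = self.integral(chrom, np.array([start, end]))
        return float((b - a) / (end - start))

    def total(self, chrom: str) -> float:
        return float(self._cum[chrom][-1]) if chrom in self._cum else 0.0


# ---------------------------------------------------------------------------
# interval algebra


def gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Signed gap between two intervals; ``None`` across chromosomes.

    Negative iff they share bases, zero iff book-ended, positive = bp apart.
    """
    if a.chrom != b.chrom:
        return None
    return max(a.start, b.start) - min(a.end, b.end)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    g = gap(a, b)
    return g is not None and g < 0


def nearest_tss(
    region: GenomicInterval,
    genes: Sequence[GeneAnnotation],
    anchor: Literal["midpoint", "edge"] = "midpoint",
) -> tuple[str, int] | None:
    """Nearest gene by TSS distance, with deterministic tie-breaking.

    Returns ``(gene_id, signed distance)`` where the distance is
    ``tss - anchor`` (negative = TSS left of the region anchor), or ``None``
    when no gene lies on the region's chromosome.  Ties on |distance| break
    by smaller TSS coordinate, then lexicographic gene id.  With
    ``anchor="edge"`` the distance is measured from the nearest region edge
    (0 if the TSS falls inside the region).
    """
    best: tuple[int, int, str, int] | None = None
    for g in genes:
        if g.body.chrom != region.chrom:
            continue
        t = g.tss_pos
        if anchor == "midpoint":
            d = t - region.midpoint
        else:
            if t < region.start:
                d = t - region.start
            elif t >= region.end:
                d = t - (region.end - 1)
            else:
                d = 0
        key = (abs(d), t, g.gene_id, d)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is None:
        return None
    return best[2], best[3]


def _promoter_window(g: GeneAnnotation, up: int, down: int) -> tuple[int, int]:
    t = g.tss_pos
    if g.body.strand == "+":
        return t - up, t + down
    return t - down + 1, t + up + 1


def classify_context(
    region: GenomicInterval,
    genes: Sequence[GeneAnnotation],
    promoter_up: int = PROMOTER_UP,
    promoter_down: int = PROMOTER_DOWN,
) -> Context:
    """Genomic context of the region midpoint: promoter > exonic > intronic > intergenic."""
    if promoter_up < 0 or promoter_down < 0:
        raise ValueError("promoter window sizes must be non-negative")
    mid = region.midpoint
    in_exon = False
    in_body = False
    for g in genes:
        if g.body.chrom != region.chrom:
            continue
        lo, hi = _promoter_window(g, promoter_up, promoter_down)
        if lo <= mid < hi:
            return "promoter"
        if g.body.start <= mid < g.body.end:
            in_body = True
            if any(e.start <= mid < e.end for e in g.exons):
                in_exon = True
    if in_exon:
        return "exonic"
    if in_body:
        return "intronic"
    return "intergenic"


# ---------------------------------------------------------------------------
# readers / writers


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file, preserving record order and coordinates."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand: Strand = "."
            if len(fields) > 5 and fields[5] in ("+", "-"):
                strand = fields[5]  # type: ignore[assignment]
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, strand, name, score)
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6; columns 4-6 are emitted for every record ('.'/0 defaults)."""
    with open(path, "w", newline="\n") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            if isinstance(score, float) and score.is_integer():
                score = int(score)
            name = iv.name if iv.name else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping runs or negative values raise ``ValueError``.
    """
    runs: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: expected 4 columns")
            try:
                runs.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return SignalTrack.from_runs(runs)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.runs(chrom)
            for s, e, v in zip(starts, ends, values):
                v = float(v)
                text = f"{int(v)}" if v.is_integer() else repr(v)
                fh.write(f"{chrom}\t{s}\t{e}\t{text}\n")


def read_annotation(
    path: str | Path, format: Literal["bed12", "gff3"] = "bed12"
) -> list[GeneAnnotation]:
    """Read gene models from BED12 or GFF3 (gene/exon features)."""
    if format == "bed12":
        return _read_bed12(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_bed12(path: str | Path) -> list[GeneAnnotation]:
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise BedParseError(f"line {lineno}: BED12 requires 12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            if strand not in ("+", "-"):
                raise BedParseError(f"line {lineno}: gene without strand, TSS undefined")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            body = GenomicInterval(chrom, start, end, strand, name)  # type: ignore[arg-type]
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + sz, strand)  # type: ignore[arg-type]
                for o, sz in zip(offsets, sizes)
            )
            out.append(GeneAnnotation(name, body, exons))
    return out


def _gff3_attr(attrs: str, *keys: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            if k in keys:
                return v
    return None


def _read_gff3(path: str | Path) -> list[GeneAnnotation]:
    genes: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise BedParseError(f"line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = f[:9]
            start, end = int(start1) - 1, int(end1)  # 1-based closed -> half-open
            if ftype == "gene":
                gid = _gff3_attr(attrs, "ID", "gene_id", "Name")
                if gid is None:
                    raise BedParseError(f"line {lineno}: gene without ID")
                if strand not in ("+", "-"):
                    raise BedParseError(
                        f"line {lineno}: gene without strand, TSS undefined"
                    )
                genes[gid] = (chrom, start, end, strand)
                order.append(gid)
            elif ftype == "exon":
                parent = _gff3_attr(attrs, "Parent", "gene_id")
                if parent is not None:
                    exons.setdefault(parent, []).append((start, end))
    out: list[GeneAnnotation] = []
    for gid in order:
        chrom, start, end, strand = genes[gid]
        body = GenomicInterval(chrom, start, end, strand, gid)  # type: ignore[arg-type]
        ex = tuple(
            GenomicInterval(chrom, s, e, strand)  # type: ignore[arg-type]
            for s, e in sorted(exons.get(gid, []))
        )
        out.append(GeneAnnotation(gid, body, ex))
    return out


def write_gff3(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            b = g.body
            fh.write(
                f"{b.chrom}\tvalleycall\tgene\t{b.start + 1}\t{b.end}\t.\t{b.strand}\t.\tID={g.gene_id}\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    f"{b.chrom}\tvalleycall\texon\t{e.start + 1}\t{e.end}\t.\t{b.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
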