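"""Alignment-free conservation scanning via shared short-word clusters.

A window on the reference is called conserved in another species when a
cluster of its 8-mers reappears, order-free, inside a single same-sized
window of that species (either strand).  Windows supported by enough
species are merged into conserved blocks.  This is a bag-of-words design:
motif rearrangements within a window do not affect the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .intervals import GenomicInterval, gap

DEFAULT_WORD = 8
DEFAULT_WINDOW = 300
DEFAULT_STEP = 50
#: Minimum distinct shared words for a species to support a window.  A
#: random 300 bp window pair shares ~2-3 8-mers by chance, but support
#: takes the best window per species, and at deep (but non-random)
#: divergence residual homology plus that maximum drives the noise floor
#: to ~10-16 shared words; deeply conserved elements contribute 35-70.
DEFAULT_MIN_SHARED = 20
DEFAULT_MIN_SPECIES = 7

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class OrthologSet:
    """One reference locus plus orthologous sequences from other species."""

    reference_species: str
    reference_seq: str
    origin: GenomicInterval
    others: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.others) < 1:
            raise ValueError("need at least 2 species in total")

    @property
    def n_species(self) -> int:
        return 1 + len(self.others)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "OrthologSet":
        """Multi-FASTA: first record is the reference with a
        ``chrom:start-end`` locus in its description."""
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) < 2:
            raise ValueError("ortholog FASTA needs >= 2 records")
        ref = records[0]
        locus = None
        for token in ref.description.split():
            if ":" in token and "-" in token.split(":")[-1]:
                chrom, span = token.rsplit(":", 1)
                try:
                    start, end = (int(x) for x in span.split("-"))
                except ValueError:
                    continue
                locus = GenomicInterval(chrom, start, end)
                break
        if locus is None:
            raise ValueError("reference description lacks a chrom:start-end locus")
        return cls(
            ref.id,
            str(ref.seq).upper(),
            locus,
            [(r.id, str(r.seq).upper()) for r in records[1:]],
        )


@dataclass
class ConservedBlock:
    """A merged run of reference windows supported by enough species."""

    window: GenomicInterval
    supporting_species: set[str]
    shared_words: dict[str, int]  # per species: max distinct shared words


def _words(seq: str, word: int) -> list[str | None]:
    """All word-mers by position; None where the window contains N."""
    return [
        seq[i : i + word] if "N" not in seq[i : i + word] else None
        for i in range(len(seq) - word + 1)
    ]


def _species_window_sets(seq: str, word: int, window: int, step: int) -> list[set[str]]:
    """Distinct words (both strands) in each sliding window of the species."""
    both = seq + "|" + reverse_complement(seq)
    out: list[set[str]] = []
    n = len(seq)
    if n < window:
        spans = [(0, n)] if n >= word else []
    else:
        starts = list(range(0, n - window + 1, step))
        if starts and starts[-1] != n - window:
            starts.append(n - window)
        spans = [(s, s + window) for s in starts]
    rc = reverse_complement(seq)
    for s, e in spans:
        ws: set[str] = set()
        for sub in (seq[s:e], rc[n - e : n - s]):
            for i in range(len(sub) - word + 1):
                w = sub[i : i + word]
                if "N" not in w:
                    ws.add(w)
        out.append(ws)
    return out


def find_conserved_blocks(
    orthologs: OrthologSet,
    word: int = DEFAULT_WORD,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_shared: int = DEFAULT_MIN_SHARED,
    min_species: int = DEFAULT_MIN_SPECIES,
) -> list[ConservedBlock]:
    """Slide a window along the reference and report conserved blocks.

    A non-reference species supports a reference window iff >= ``min_shared``
    of the window's distinct ``word``-mers co-occur within one
    ``window``-sized stretch of that species (either strand).  Windows
    supported by >= ``min_species`` species (the reference always supports
    itself) are merged into blocks; coordinates are reported on the
    reference genome via the locus ``origin``.
    """
    if word > window:
        raise ValueError("word must not exceed window")
    ref = orthologs.reference_seq
    if len(ref) < window:
        raise ValueError("reference shorter than one window")
    species_sets = {
        name: _species_window_sets(seq, word, window, step)
        for name, seq in orthologs.others
    }
    starts = list(range(0, len(ref) - window + 1, step))
    if starts[-1] != len(ref) - window:
        starts.append(len(ref) - window)

    supported: list[tuple[int, int, set[str], dict[str, int]]] = []
    for s in starts:
        ref_words = {
            w for w in _words(ref[s : s + window], word) if w is not None
        }
        if not ref_words:
            continue
        supp: set[str] = set()
        shared: dict[str, int] = {}
        for name, windows in species_sets.items():
            best = max(
                (len(ref_words & ws) for ws in windows), default=0
            )
            shared[name] = best
            if best >= min_shared:
                supp.add(name)
        if 1 + len(supp) >= min_species:  # reference supports itself
            supported.append((s, s + window, supp, shared))

    blocks: list[ConservedBlock] = []
    origin = orthologs.origin
    for s, e, supp, shared in supported:
        iv = GenomicInterval(origin.chrom, origin.start + s, origin.start + e)
        if blocks and blocks[-1].window.end >= iv.start:
            last = blocks[-1]
            last.window = GenomicInterval(
                iv.chrom, last.window.start, max(last.window.end, iv.end)
            )
            last.supporting_species |= supp
            for k, v in shared.items():
                last.shared_words[k] = max(last.shared_words.get(k, 0), v)
        else:
            blocks.append(
                ConservedBlock(iv, set(supp) | {orthologs.reference_species}, dict(shared))
            )
    return blocks


def annotate_blocks(blocks: Sequence[ConservedBlock], enhancers) -> "pd.DataFrame":
    """Per-enhancer conserved/not flag using the 0 bp gap rule."""
    import pandas as pd

    rows = []
    for e in enhancers:
        v = e.valley
        conserved = any(
            (g := gap(v, b.window)) is not None and g <= 0 for b in blocks
        )
        rows.append(
            {
                "chrom": v.chrom,
                "start": v.start,
                "end": v.end,
                "gene_id": e.gene_id,
                "condition": e.condition,
                "conserved": conserved,
            }
        )
    return pd.DataFrame(rows)
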