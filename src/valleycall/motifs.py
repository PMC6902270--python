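"""PWM scanning with exact score p-values and shuffle-null motif enrichment.

A :class:`PWM` is a position count matrix with pseudocount and background;
scores are log2 odds in bits.  The score threshold for a target p-value is
computed exactly by dynamic programming over the integer-rescaled score
distribution (the classical lattice method), sequences are scanned on both
strands, and set-level enrichment is tested against a mononucleotide- (or
dinucleotide-) shuffle null with the add-one empirical p-value rule
``p = (1 + #{null >= observed}) / (1 + #null)``.

The set statistic is the log of the average likelihood ratio over all
windows and strands (a raw-score statistic in the style of Clover),
averaged over sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .intervals import GenomicInterval

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
SCORE_SCALE = 1e-3  # bits per lattice unit in the threshold DP
MAX_EXACT_WIDTH = 25


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over A,C,G,T with background model.

    ``counts`` has shape (width, 4).  Column probabilities are
    ``(counts + pseudocount * background) / (column_total + pseudocount)``
    and log-odds are log2(prob / background) in bits.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 1.0
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be width x 4 (A,C,G,T)")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 positive probabilities summing to 1")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        return (self.counts + self.pseudocount * self.background) / (
            totals + self.pseudocount
        )

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.name,
            self.counts[::-1, ::-1],
            self.pseudocount,
            self.background[::-1],
        )

    def consensus(self, rng: np.random.Generator | None = None) -> str:
        """A maximum-score word; ties broken uniformly at random if ``rng`` given."""
        lo = self.log_odds
        letters = []
        for row in lo:
            idx = np.flatnonzero(row == row.max())
            pick = idx[0] if rng is None else int(rng.choice(idx))
            letters.append(BASES[pick])
        return "".join(letters)

    def quantised_log_odds(self, scale: float = SCORE_SCALE) -> np.ndarray:
        """Integer lattice version of the log-odds matrix (units of ``scale`` bits)."""
        return np.rint(self.log_odds / scale).astype(np.int64)


@dataclass(frozen=True)
class MotifHit:
    """One scored PWM match; coordinates are 0-based on the forward strand."""

    location: GenomicInterval
    strand: Literal["+", "-"]
    score: float


@dataclass
class EnrichmentResult:
    pwm_name: str
    observed_stat: float
    null_stats: np.ndarray
    p_value: float


def read_jaspar(path: str | Path, pseudocount: float = 1.0) -> list[PWM]:
    """Read JASPAR pfm/jaspar-format count matrices via Biopython."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        name = m.name or m.matrix_id or "motif"
        out.append(PWM(str(name), counts, pseudocount))
    return out


def write_jaspar(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in p.counts[:, bi])
                fh.write(f"{base} [ {row} ]\n")


def ap1_fixture(name: str = "AP1_fixture") -> PWM:
    """Synthetic AP1 (Jun:Fos) count matrix built from the TGA(C/G)TCA consensus.

    A test fixture, not published data: 18 pseudo-observations per column
    with the consensus base dominant and the central position split C/G.
    """
    strong = [
        [1, 1, 1, 15],  # T
        [1, 1, 15, 1],  # G
        [15, 1, 1, 1],  # A
        [1, 9, 7, 1],   # C/G, C slightly favoured
        [1, 1, 1, 15],  # T
        [1, 15, 1, 1],  # C
        [15, 1, 1, 1],  # A
    ]
    return PWM(name, np.array(strong, dtype=float))


# ---------------------------------------------------------------------------
# exact score-threshold DP


def score_distribution(pwm: PWM, scale: float = SCORE_SCALE) -> tuple[np.ndarray, int]:
    """Exact background distribution of the lattice-quantised word score.

    Returns ``(probs, offset)`` where ``probs[i]`` is the probability that a
    random background word scores ``(offset + i) * scale`` bits.
    """
    if pwm.width > MAX_EXACT_WIDTH:
        raise ValueError(
            f"width {pwm.width} > {MAX_EXACT_WIDTH}: exact DP refused, use sampling"
        )
    q = pwm.quantised_log_odds(scale)
    bg = pwm.background
    lo_total = int(q.min(axis=1).sum())
    hi_total = int(q.max(axis=1).sum())
    probs = np.zeros(hi_total - lo_total + 1)
    # start: empty word at score 0, tracked relative to running minimum
    cur = np.array([1.0])
    cur_lo = 0
    for row in q:
        row_lo, row_hi = int(row.min()), int(row.max())
        new = np.zeros(len(cur) + row_hi - row_lo)
        for b in range(4):
            shift = int(row[b]) - row_lo
            new[shift : shift + len(cur)] += bg[b] * cur
        cur = new
        cur_lo += row_lo
    probs[cur_lo - lo_total : cur_lo - lo_total + len(cur)] = cur
    return probs, lo_total


def score_threshold(pwm: PWM, p: float, scale: float = SCORE_SCALE) -> float:
    """Smallest score s (bits) with P(random word score >= s) <= p, exactly.

    Computed on the integer score lattice (``scale`` bits per unit); exact
    for the quantised scores, so the returned threshold is accurate to
    ``width * scale / 2`` bits.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    probs, offset = score_distribution(pwm, scale)
    tail = np.cumsum(probs[::-1])[::-1]
    attained = np.flatnonzero(probs > 0)
    ok = attained[tail[attained] <= p + 1e-12]
    if len(ok) == 0:
        # only scores above the maximum attainable satisfy the bound
        return (offset + attained[-1] + 1) * scale
    return (offset + ok[0]) * scale


# ---------------------------------------------------------------------------
# scanning


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to codes A=0,C=1,G=2,T=3; anything else (N) = -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, i in _CODE.items():
        codes[arr == ord(base)] = i
    return codes


def window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score NaN."""
    w = log_odds.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for j in range(w):
        col = codes[j : j + n]
        bad |= col < 0
        scores += log_odds[j, np.clip(col, 0, 3)]
    scores[bad] = np.nan
    return scores


def scan(
    seq: str,
    pwm: PWM,
    threshold: float,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """All positions x strands scoring >= threshold bits.

    The reverse strand is scored on the reverse complement; reported
    coordinates are 0-based forward-strand positions (plus ``offset``).
    """
    codes = encode(seq)
    hits: list[MotifHit] = []
    w = pwm.width
    # score on the same lattice the threshold DP uses, so threshold
    # comparisons are exact rather than float-rounding sensitive
    lo_fwd = pwm.quantised_log_odds() * SCORE_SCALE
    lo_rev = pwm.reverse_complement().quantised_log_odds() * SCORE_SCALE
    for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
        scores = window_scores(codes, lo)
        keep = ~np.isnan(scores) & (scores >= threshold - 1e-9)
        for i in np.flatnonzero(keep):
            hits.append(
                MotifHit(
                    GenomicInterval(
                        chrom,
                        offset + int(i),
                        offset + int(i) + w,
                        strand,  # type: ignore[arg-type]
                        name=pwm.name,
                        score=float(scores[i]),
                    ),
                    strand,  # type: ignore[arg-type]
                    float(scores[i]),
                )
            )
    hits.sort(key=lambda h: (h.location.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# shuffle-null enrichment


def _sequence_stat(codes: np.ndarray, lo_fwd: np.ndarray, lo_rev: np.ndarray) -> float:
    """log(average over all windows and strands of 2**score) for one sequence."""
    s = np.concatenate(
        [window_scores(codes, lo_fwd), window_scores(codes, lo_rev)]
    )
    s = s[~np.isnan(s)]
    if len(s) == 0:
        return np.nan
    # log-mean-exp in base 2 scores, natural-log output
    m = s.max()
    return float(np.log(np.exp2(s - m).mean()) + m * np.log(2.0))


def set_statistic(seqs: Sequence[str], pwm: PWM) -> float:
    """Mean per-sequence raw-score statistic over a sequence set."""
    lo_f = pwm.log_odds
    lo_r = pwm.reverse_complement().log_odds
    vals = [_sequence_stat(encode(s), lo_f, lo_r) for s in seqs]
    vals = [v for v in vals if not np.isnan(v)]
    if not vals:
        raise ValueError("all sequences shorter than the PWM width")
    return float(np.mean(vals))


def _shuffle(codes: np.ndarray, rng: np.random.Generator, mode: str) -> np.ndarray:
    if mode == "mono":
        return rng.permutation(codes)
    if mode == "dinuc":
        return _dinucleotide_shuffle(codes, rng)
    raise ValueError(f"unknown shuffle mode {mode!r}")


def _dinucleotide_shuffle(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Composition-preserving dinucleotide shuffle (Altschul-Erikson style).

    Keeps the multiset of adjacent pairs; N positions are left in place.
    """
    valid = codes[codes >= 0]
    if len(valid) < 3:
        return codes.copy()
    edges: dict[int, list[int]] = {b: [] for b in range(4)}
    for a, b in zip(valid[:-1], valid[1:]):
        edges[int(a)].append(int(b))
    first, last = int(valid[0]), int(valid[-1])
    for _ in range(50):
        trial = {a: list(rng.permutation(bs)) for a, bs in edges.items()}
        # ensure the walk can end at `last`: move one edge into terminal position
        path = [first]
        pos = {a: 0 for a in range(4)}
        cur = first
        ok = True
        for _step in range(len(valid) - 1):
            lst = trial[cur]
            if pos[cur] >= len(lst):
                ok = False
                break
            nxt = lst[pos[cur]]
            pos[cur] += 1
            path.append(nxt)
            cur = nxt
        if ok and len(path) == len(valid):
            out = codes.copy()
            out[codes >= 0] = path
            return out
    return rng.permutation(codes)  # fallback for pathological compositions


def shuffle_enrichment(
    seqs: Sequence[str],
    pwm: PWM,
    n_shuffles: int = 1000,
    seed: int = 0,
    shuffle_mode: Literal["mono", "dinuc"] = "mono",
) -> EnrichmentResult:
    """Empirical enrichment of a PWM in a sequence set vs shuffled versions.

    Each null replicate shuffles every sequence independently (composition
    preserving) and recomputes the set statistic; add-one p-value rule.
    """
    if n_shuffles < 99:
        raise ValueError("n_shuffles must be >= 99")
    if not seqs:
        raise ValueError("empty sequence set")
    rng = np.random.default_rng(seed)
    lo_f = pwm.log_odds
    lo_r = pwm.reverse_complement().log_odds
    all_codes = [encode(s) for s in seqs]
    usable = [c for c in all_codes if len(c) >= pwm.width]
    if not usable:
        raise ValueError("all sequences shorter than the PWM width")
    observed = float(
        np.mean([_sequence_stat(c, lo_f, lo_r) for c in usable])
    )
    null = np.empty(n_shuffles)
    for r in range(n_shuffles):
        vals = [
            _sequence_stat(_shuffle(c, rng, shuffle_mode), lo_f, lo_r)
            for c in usable
        ]
        null[r] = np.mean(vals)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_shuffles)
    return EnrichmentResult(pwm.name, observed, null, p)


def differential_motif_enrichment(
    set_a: Sequence[str],
    set_b: Sequence[str],
    pwms: Sequence[PWM],
    n_shuffles: int = 1000,
    seed: int = 0,
    e_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-PWM a-vs-b enrichment with a pooled re-splitting null.

    Statistic: set_statistic(a) - set_statistic(b).  The null pools both
    sets and randomly re-splits into the original sizes; the per-PWM
    e-value is the Bonferroni-style ``p * n_pwms``, flagged significant at
    ``e <= e_threshold``.
    """
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be non-empty")
    rng = np.random.default_rng(seed)
    pooled = [encode(s) for s in list(set_a) + list(set_b)]
    n_a = len(set_a)
    los = [(p.log_odds, p.reverse_complement().log_odds) for p in pwms]

    def stats_for(split: Sequence[np.ndarray], lo_f, lo_r, width) -> float:
        vals = [
            _sequence_stat(c, lo_f, lo_r) for c in split if len(c) >= width
        ]
        return float(np.mean(vals)) if vals else np.nan

    observed = np.array(
        [
            stats_for(pooled[:n_a], f, r, p.width)
            - stats_for(pooled[n_a:], f, r, p.width)
            for p, (f, r) in zip(pwms, los)
        ]
    )
    null = np.empty((n_shuffles, len(pwms)))
    for rep in range(n_shuffles):
        perm = rng.permutation(len(pooled))
        ia, ib = perm[:n_a], perm[n_a:]
        for k, (p, (f, r)) in enumerate(zip(pwms, los)):
            null[rep, k] = stats_for(
                [pooled[i] for i in ia], f, r, p.width
            ) - stats_for([pooled[i] for i in ib], f, r, p.width)
    pvals = (1 + (null >= observed).sum(axis=0)) / (1 + n_shuffles)
    evals = pvals * len(pwms)
    return pd.DataFrame(
        {
            "pwm": [p.name for p in pwms],
            "observed_stat": observed,
            "p_value": pvals,
            "e_value": evals,
            "significant": evals <= e_threshold,
        }
    )
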