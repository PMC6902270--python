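"""Synthetic-data generators with recorded ground truth for every stage.

Emulates the study conditions the pipeline was built for: two-condition
(control vs FGF-treated) H3K27ac/H3K27me3 peak sets with planted bimodal
enhancer valleys and edge jitter, coverage tracks with peak-dip-peak TSS
acetylation, AP1-motif planting into FGF-condition valleys, ortholog
sequence sets with deeply conserved short elements, and negative-binomial
nCounter-like count tables with planted direct/indirect/repressed FGF
responses.  Every generator is fully deterministic given its seed, and the
recorded :class:`SyntheticTruth` suffices to score each pipeline stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .enhancers import PutativeEnhancer
from .expression import CountTable
from .intervals import GeneAnnotation, GenomicInterval, SignalTrack
from .motifs import PWM

log = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype="S1")
CONDITIONS = ("CNT", "FGF")
DEFAULT_SPECIES = (
    "human",
    "horse",
    "cow",
    "rabbit",
    "mouse",
    "opossum",
    "platypus",
    "chick",
    "lizard",
)


@dataclass(frozen=True)
class PlantedEnhancer:
    valley: GenomicInterval
    target_gene: str
    conditions: tuple[str, ...]
    has_ap1: bool = False


@dataclass
class SyntheticTruth:
    """Planted ground truth against which every pipeline stage is scored."""

    seed: int
    genome: dict[str, str]
    genes: list[GeneAnnotation]
    enhancers: list[PlantedEnhancer] = field(default_factory=list)
    motif_sites: list[GenomicInterval] = field(default_factory=list)
    conserved_blocks: list[GenomicInterval] = field(default_factory=list)
    response: pd.Series | None = None

    def enhancers_of(self, condition: str) -> list[PlantedEnhancer]:
        return [e for e in self.enhancers if condition in e.conditions]


# ---------------------------------------------------------------------------
# genome and genes


def generate_genome(
    seed: int,
    n_chrom: int = 1,
    chrom_length: int = 1_000_000,
    gc: float = 0.42,
    gene_density: float = 1 / 25_000,
    gene_length: tuple[int, int] = (2_000, 8_000),
) -> SyntheticTruth:
    """I.i.d. genome at the stated GC with non-overlapping random genes.

    Genes get random strands and 2-4 exons.  Raises when the requested
    density cannot be placed without overlap.
    """
    if chrom_length < 50_000:
        raise ValueError("chrom_length must be >= 50 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: dict[str, str] = {}
    genes: list[GeneAnnotation] = []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(BASES, size=chrom_length, p=p)
        genome[chrom] = seq.tobytes().decode("ascii")
        n_genes = int(round(gene_density * chrom_length))
        placed: list[tuple[int, int]] = []
        for gi in range(n_genes):
            length = int(rng.integers(gene_length[0], gene_length[1] + 1))
            ok = False
            for _try in range(200):
                start = int(rng.integers(1_000, chrom_length - length - 1_000))
                if all(start >= e + 1_000 or start + length <= s - 1_000 for s, e in placed):
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"gene density {gene_density} too high for {chrom_length} bp"
                )
            placed.append((start, start + length))
            strand = "+" if rng.random() < 0.5 else "-"
            body = GenomicInterval(chrom, start, start + length, strand)
            n_ex = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(200, length - 200, 100), 2 * n_ex, replace=False))
            exons = tuple(
                GenomicInterval(chrom, start + int(cuts[2 * k]), start + int(cuts[2 * k + 1]), strand)
                for k in range(n_ex)
            )
            genes.append(GeneAnnotation(f"gene_{chrom}_{gi:03d}", body, exons))
    return SyntheticTruth(seed=seed, genome=genome, genes=genes)


# ---------------------------------------------------------------------------
# enhancer planting


@dataclass
class PlantResult:
    """BED peak sets, coverage tracks and updated truth from plant_enhancers."""

    ac_peaks: dict[str, list[GenomicInterval]]  # condition -> H3K27ac peaks
    me3_peaks: dict[str, list[GenomicInterval]]  # condition -> H3K27me3 peaks
    ac_tracks: dict[str, SignalTrack]
    me3_tracks: dict[str, SignalTrack]
    truth: SyntheticTruth


def plant_enhancers(
    truth: SyntheticTruth,
    seed: int,
    n_per_condition: int = 40,
    common_fraction: float = 0.2,
    jitter_sd: float = 30.0,
    n_decoy_repressed: int = 5,
    valley_range: tuple[int, int] = (200, 2_500),
    flank_range: tuple[int, int] = (500, 1_500),
    coverage_bin: int = 25,
) -> PlantResult:
    """Plant condition-specific valleys with flanking acetylation.

    Each planted enhancer is a valley (``valley_range`` bp) between two
    H3K27ac flank peaks (``flank_range`` bp each) near a designated target
    gene.  Peak BED records are the true flanks with Gaussian edge jitter
    (truncated so flanks never invade more than 25% of the valley).  Decoy
    valleys covered by an H3K27me3 domain are planted per condition (these
    must be rejected by the caller and are not part of the truth), and
    H3K27me3 domains are placed over repressed-gene loci in the FGF
    condition.  Coverage tracks get flank plateaus with Poisson noise and a
    peak-dip-peak acetylation profile at every TSS.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_common = int(round(common_fraction * n_per_condition))
    n_unique = n_per_condition - n_common
    plan = (
        [("CNT",)] * n_unique + [("FGF",)] * n_unique + [("CNT", "FGF")] * n_common
    )
    # physical occupancy (avoid overlapping structures/genes) plus
    # per-condition occupancy with a > max-inner-gap pad so that flank
    # peaks of different structures can never pair into a spurious valley
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in truth.genome}
    by_cond: dict[str, dict[str, list[tuple[int, int]]]] = {
        cond: {c: [] for c in truth.genome} for cond in CONDITIONS
    }
    for g in truth.genes:
        occupied[g.body.chrom].append((g.body.start, g.body.end))

    def clear(spans: list[tuple[int, int]], start: int, end: int, pad: int) -> bool:
        return all(start >= e + pad or end <= s - pad for s, e in spans)

    def usable(chrom: str, start: int, length: int, conds: tuple[str, ...], cond_pad: int = 3_500) -> bool:
        end = start + length
        if start < 2_000 or end > len(truth.genome[chrom]) - 2_000:
            return False
        return clear(occupied[chrom], start, end, 300) and all(
            clear(by_cond[c][chrom], start, end, cond_pad) for c in conds
        )

    def book(chrom: str, start: int, length: int, conds: tuple[str, ...]) -> None:
        occupied[chrom].append((start, start + length))
        for c in conds:
            by_cond[c][chrom].append((start, start + length))

    def reserve(chrom: str, length: int, conds: tuple[str, ...]) -> int | None:
        for _try in range(2_000):
            start = int(rng.integers(2_000, len(truth.genome[chrom]) - length - 2_000))
            if usable(chrom, start, length, conds):
                book(chrom, start, length, conds)
                return start
        return None

    from .intervals import nearest_tss

    chroms = sorted(truth.genome)
    gene_pool = list(truth.genes)
    rng.shuffle(gene_pool)  # type: ignore[arg-type]
    planted: list[PlantedEnhancer] = []
    structures: list[tuple[str, int, int, int, int, tuple[str, ...]]] = []
    for conds in plan:
        lf = int(rng.integers(*flank_range))
        rf = int(rng.integers(*flank_range))
        vl = int(rng.integers(*valley_range))
        length = lf + vl + rf
        # place near a designated target gene such that nearest-TSS
        # assignment of the valley recovers exactly that gene
        start = target = None
        while gene_pool and start is None:
            cand = gene_pool.pop()
            chrom = cand.body.chrom
            t = cand.tss_pos
            for _try in range(60):
                offset = int(rng.integers(3_000, 12_000)) * (1 if rng.random() < 0.5 else -1)
                mid = t + offset
                s = mid - lf - vl // 2
                if not usable(chrom, s, length, conds):
                    continue
                v = GenomicInterval(chrom, s + lf, s + lf + vl)
                hit = nearest_tss(v, truth.genes)
                if hit is not None and hit[0] == cand.gene_id:
                    start, target = s, cand
                    book(chrom, s, length, conds)
                    break
        if start is None:
            # fall back to an unanchored placement far from any structure
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = reserve(chrom, length, conds)
            if start is None:
                raise ValueError("no room to place flanks; lower n_per_condition")
            target = truth.genes[0]
            hit = nearest_tss(GenomicInterval(chrom, start + lf, start + lf + vl), truth.genes)
            if hit is not None:
                target = next(g for g in truth.genes if g.gene_id == hit[0])
        valley = GenomicInterval(chrom, start + lf, start + lf + vl)
        planted.append(PlantedEnhancer(valley, target.gene_id, conds))
        structures.append((chrom, start, lf, vl, rf, conds))

    # decoy bimodal pairs whose valley carries H3K27me3 (must be filtered out)
    decoys: dict[str, list[tuple[str, int, int, int, int]]] = {c: [] for c in CONDITIONS}
    for cond in CONDITIONS:
        for _ in range(n_decoy_repressed):
            chrom = chroms[int(rng.integers(len(chroms)))]
            lf, rf = (int(rng.integers(*flank_range)) for _ in range(2))
            vl = int(rng.integers(*valley_range))
            start = reserve(chrom, lf + vl + rf, (cond,))
            if start is None:
                continue
            decoys[cond].append((chrom, start, lf, vl, rf))

    # H3K27me3 domains over repressed genes in the FGF condition
    enhancer_targets = {e.target_gene for e in planted}
    repressed = [g for g in truth.genes if g.gene_id not in enhancer_targets][:8]
    me3_domains: dict[str, list[GenomicInterval]] = {c: [] for c in CONDITIONS}
    for g in repressed:
        t = g.tss_pos
        lo = max(0, t - int(rng.integers(1_000, 3_000)))
        hi = min(len(truth.genome[g.body.chrom]), t + int(rng.integers(1_000, 3_000)))
        me3_domains["FGF"].append(GenomicInterval(g.body.chrom, lo, hi))

    def jitter_edge(x: int, lo: int, hi: int) -> int:
        j = int(round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
        return int(np.clip(x + j, lo, hi))

    ac_peaks: dict[str, list[GenomicInterval]] = {c: [] for c in CONDITIONS}
    me3_peaks: dict[str, list[GenomicInterval]] = {c: [] for c in CONDITIONS}
    for cond in CONDITIONS:
        for chrom, start, lf, vl, rf, conds in structures + [
            d + ((cond,),) for d in decoys[cond]
        ]:
            if cond not in conds:
                continue
            invade = vl // 4
            l0, l1 = start, start + lf
            r0, r1 = start + lf + vl, start + lf + vl + rf
            jl0 = jitter_edge(l0, max(0, l0 - 200), l1 - 50)
            jl1 = jitter_edge(l1, jl0 + 50, l1 + invade)
            jr0 = jitter_edge(r0, r0 - invade, r1 - 50)
            jr1 = jitter_edge(r1, jr0 + 50, r1 + 200)
            ac_peaks[cond].append(GenomicInterval(chrom, jl0, jl1))
            ac_peaks[cond].append(GenomicInterval(chrom, jr0, jr1))
        for chrom, start, lf, vl, rf in decoys[cond]:
            pad = min(100, vl // 4)
            me3_peaks[cond].append(
                GenomicInterval(chrom, start + lf + pad, start + lf + vl - pad)
            )
        me3_peaks[cond].extend(me3_domains[cond])
        ac_peaks[cond].sort(key=lambda p: (p.chrom, p.start))
        me3_peaks[cond].sort(key=lambda p: (p.chrom, p.start))

    ac_tracks, me3_tracks = _coverage_tracks(
        truth, structures, decoys, me3_peaks, rng, coverage_bin
    )
    truth.enhancers = planted
    return PlantResult(ac_peaks, me3_peaks, ac_tracks, me3_tracks, truth)


def _coverage_tracks(
    truth: SyntheticTruth,
    structures,
    decoys,
    me3_peaks,
    rng: np.random.Generator,
    bin_size: int,
    bg_ac: float = 1.0,
    bg_me3: float = 0.5,
    h_peak: float = 20.0,
    h_valley: float = 2.0,
    h_tss: float = 15.0,
    h_me3: float = 10.0,
) -> tuple[dict[str, SignalTrack], dict[str, SignalTrack]]:
    ac_tracks: dict[str, SignalTrack] = {}
    me3_tracks: dict[str, SignalTrack] = {}
    for cond in CONDITIONS:
        ac_runs: list[tuple[str, int, int, float]] = []
        me3_runs: list[tuple[str, int, int, float]] = []
        for chrom, seq in sorted(truth.genome.items()):
            n_bins = len(seq) // bin_size
            lam_ac = np.full(n_bins, bg_ac)
            lam_me3 = np.full(n_bins, bg_me3)

            def paint(lam: np.ndarray, start: int, end: int, height: float) -> None:
                b0, b1 = max(0, start // bin_size), min(n_bins, -(-end // bin_size))
                lam[b0:b1] = height

            # peak-dip-peak acetylation at every TSS (both conditions)
            for g in truth.genes:
                if g.body.chrom != chrom:
                    continue
                t = g.tss_pos
                paint(lam_ac, t - 600, t - 100, h_tss)
                paint(lam_ac, t + 100, t + 600, h_tss)
                paint(lam_ac, t - 100, t + 100, h_valley)
            for schrom, start, lf, vl, rf, conds in structures:
                if schrom != chrom or cond not in conds:
                    continue
                paint(lam_ac, start, start + lf, h_peak)
                paint(lam_ac, start + lf, start + lf + vl, h_valley)
                paint(lam_ac, start + lf + vl, start + lf + vl + rf, h_peak)
            for dchrom, start, lf, vl, rf in decoys[cond]:
                if dchrom != chrom:
                    continue
                paint(lam_ac, start, start + lf, h_peak)
                paint(lam_ac, start + lf + vl, start + lf + vl + rf, h_peak)
            for m in me3_peaks[cond]:
                if m.chrom == chrom:
                    paint(lam_me3, m.start, m.end, h_me3)

            ac_vals = rng.poisson(lam_ac).astype(float)
            me3_vals = rng.poisson(lam_me3).astype(float)
            for b in range(n_bins):
                if ac_vals[b] > 0:
                    ac_runs.append((chrom, b * bin_size, (b + 1) * bin_size, ac_vals[b]))
                if me3_vals[b] > 0:
                    me3_runs.append((chrom, b * bin_size, (b + 1) * bin_size, me3_vals[b]))
        ac_tracks[cond] = SignalTrack.from_runs(ac_runs)
        me3_tracks[cond] = SignalTrack.from_runs(me3_runs)
    return ac_tracks, me3_tracks


# ---------------------------------------------------------------------------
# motif planting


def plant_motifs(
    truth: SyntheticTruth,
    pwm: PWM,
    fraction_fgf: float = 0.6,
    seed: int = 0,
) -> SyntheticTruth:
    """Write a maximum-score PWM word into a fraction of FGF-unique valleys.

    Control valleys receive none; planted positions and strands are
    recorded in ``truth.motif_sites``.  Valleys narrower than the motif are
    skipped with a log entry.
    """
    if not 0 <= fraction_fgf <= 1:
        raise ValueError("fraction_fgf must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fgf_only = [
        e for e in truth.enhancers if e.conditions == ("FGF",)
    ]
    n_plant = int(round(fraction_fgf * len(fgf_only)))
    chosen = list(rng.choice(len(fgf_only), size=n_plant, replace=False)) if n_plant else []
    sites: list[GenomicInterval] = []
    new_enh = list(truth.enhancers)
    for idx in sorted(int(i) for i in chosen):
        e = fgf_only[idx]
        w = pwm.width
        if e.valley.length < w:
            log.warning("valley %s narrower than motif, skipped", e.valley)
            continue
        word = pwm.consensus(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            from .conservation import reverse_complement

            word = reverse_complement(word)
        pos = e.valley.start + int(rng.integers(0, e.valley.length - w + 1))
        chrom_seq = truth.genome[e.valley.chrom]
        truth.genome[e.valley.chrom] = (
            chrom_seq[:pos] + word + chrom_seq[pos + w :]
        )
        sites.append(
            GenomicInterval(e.valley.chrom, pos, pos + w, strand, name=pwm.name)  # type: ignore[arg-type]
        )
        new_enh[new_enh.index(e)] = replace(e, has_ap1=True)
    truth.enhancers = new_enh
    truth.motif_sites = sites
    return truth


def valley_sequences(truth: SyntheticTruth, condition: str) -> list[str]:
    """Valley DNA of all planted enhancers present in a condition."""
    return [
        truth.genome[e.valley.chrom][e.valley.start : e.valley.end]
        for e in truth.enhancers_of(condition)
    ]


# ---------------------------------------------------------------------------
# orthologs


def make_orthologs(
    truth: SyntheticTruth,
    species: Sequence[str] = DEFAULT_SPECIES,
    conserved_fraction: float = 0.05,
    per_species_divergence: float = 0.45,
    conserved_in: int = 8,
    element_length: int = 80,
    locus_length: int = 4_000,
    seed: int = 0,
):
    """Ortholog sequences for one reference locus with planted conserved elements.

    The reference is a slice of the truth genome (over the first
    FGF-condition valley when one exists).  Non-reference species are
    i.i.d.-substituted copies at ``per_species_divergence``; planted
    elements are re-copied with 1% substitution into ``conserved_in - 1``
    other species at a random location each (order/position-free, as an
    alignment-free scan should tolerate).  Returns an
    :class:`~valleycall.conservation.OrthologSet`; planted spans land in
    ``truth.conserved_blocks``.
    """
    from .conservation import OrthologSet

    if not 0 <= per_species_divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    chrom = sorted(truth.genome)[0]
    anchor = None
    for e in truth.enhancers:
        if "FGF" in e.conditions and e.valley.chrom == chrom:
            anchor = e.valley.midpoint
            break
    if anchor is None:
        anchor = len(truth.genome[chrom]) // 2
    start = int(np.clip(anchor - locus_length // 2, 0, len(truth.genome[chrom]) - locus_length))
    ref = truth.genome[chrom][start : start + locus_length]
    origin = GenomicInterval(chrom, start, start + locus_length)

    n_elements = max(1, int(round(conserved_fraction * locus_length / element_length)))
    margin = 200
    positions: list[int] = []
    for _ in range(n_elements):
        for _try in range(200):
            pos = int(rng.integers(margin, locus_length - element_length - margin))
            if all(abs(pos - p) >= element_length + 400 for p in positions):
                positions.append(pos)
                break
    elements = [(p, ref[p : p + element_length]) for p in sorted(positions)]

    def mutate(seq: str, rate: float) -> str:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hit = rng.random(len(arr)) < rate
        for i in np.flatnonzero(hit):
            choices = [b for b in BASES if b != arr[i]]
            arr[i] = choices[int(rng.integers(3))]
        return arr.tobytes().decode()

    others: list[tuple[str, str]] = []
    carriers = list(species[1 : conserved_in])  # reference carries by construction
    for name in species[1:]:
        seq = mutate(ref, per_species_divergence)
        if name in carriers:
            for pos, elem in elements:
                copy = mutate(elem, 0.01)
                where = int(rng.integers(0, len(seq) - len(copy) + 1))
                seq = seq[:where] + copy + seq[where + len(copy) :]
        others.append((name, seq))

    truth.conserved_blocks = [
        GenomicInterval(chrom, start + p, start + p + element_length)
        for p, _ in elements
    ]
    return OrthologSet(species[0], ref, origin, others)


# ---------------------------------------------------------------------------
# expression counts


@dataclass(frozen=True)
class CountDesign:
    """Design of the simulated multiplexed count experiment."""

    conditions: tuple[str, ...] = ("CNT", "FGF", "CHX", "FGF_CHX")
    replicates: int = 3
    n_direct_up: int = 10
    n_direct_down: int = 10
    n_indirect_up: int = 10
    n_indirect_down: int = 10
    n_unresponsive: int = 160
    n_positive: int = 6
    n_negative: int = 8
    n_housekeeping: int = 10
    log2_fc: float = 2.0
    dispersion: float = 0.1
    #: spike-in (positive/negative) probes carry technical noise only
    technical_dispersion: float = 0.01
    lane_effect_sd: float = 0.15
    baseline_range: tuple[float, float] = (500.0, 5_000.0)


def simulate_counts(
    design: CountDesign | None = None, seed: int = 0
) -> tuple[CountTable, pd.Series]:
    """Negative-binomial count table with planted FGF response classes.

    Direct targets carry the planted fold change in both the FGF-vs-CNT and
    FGF_CHX-vs-CHX contrasts; indirect targets only in FGF-vs-CNT; *down*
    classes are mirrored.  Positive, negative and housekeeping probes are
    included with per-sample lane-effect multipliers so that
    :func:`~valleycall.expression.normalize` has real work to do.  Returns
    the table and the probe -> planted-class truth.
    """
    design = design or CountDesign()
    required = {"CNT", "FGF", "CHX", "FGF_CHX"}
    if not required.issubset(design.conditions):
        raise ValueError(f"design must name conditions {sorted(required)}")
    if design.replicates < 3:
        raise ValueError("need >= 3 replicates")
    rng = np.random.default_rng(seed)

    classes = (
        ["direct_up"] * design.n_direct_up
        + ["direct_down"] * design.n_direct_down
        + ["indirect_up"] * design.n_indirect_up
        + ["indirect_down"] * design.n_indirect_down
        + ["unresponsive"] * design.n_unresponsive
    )
    probes = [f"probe_{i:03d}" for i in range(len(classes))]
    truth = pd.Series(classes, index=probes, name="planted_class")

    samples, conds, reps = [], [], []
    for c in design.conditions:
        for r in range(1, design.replicates + 1):
            samples.append(f"{c}:{r}")
            conds.append(c)
            reps.append(r)
    lane = np.exp(rng.normal(0.0, design.lane_effect_sd, len(samples)))
    content = np.exp(rng.normal(0.0, design.lane_effect_sd, len(samples)))

    lo, hi = np.log(design.baseline_range[0]), np.log(design.baseline_range[1])
    baseline = np.exp(rng.uniform(lo, hi, len(probes)))
    fc = 2.0 ** design.log2_fc

    def nb(mean: np.ndarray, dispersion: float | None = None) -> np.ndarray:
        disp = design.dispersion if dispersion is None else dispersion
        mean = np.maximum(mean, 1e-6)
        if disp <= 0:
            return rng.poisson(mean).astype(float)
        n = 1.0 / disp
        return rng.negative_binomial(n, n / (n + mean)).astype(float)

    rows = {}
    for probe, cls, base in zip(probes, classes, baseline):
        mult = {c: 1.0 for c in design.conditions}
        if cls == "direct_up":
            mult["FGF"] = fc
            mult["FGF_CHX"] = fc
        elif cls == "direct_down":
            mult["FGF"] = 1 / fc
            mult["FGF_CHX"] = 1 / fc
        elif cls == "indirect_up":
            mult["FGF"] = fc
        elif cls == "indirect_down":
            mult["FGF"] = 1 / fc
        means = np.array(
            [base * mult[c] * lane[s] * content[s] for s, c in enumerate(conds)]
        )
        rows[probe] = nb(means)

    pos_ladder = 128 * 4.0 ** np.arange(design.n_positive)
    for i in range(design.n_positive):
        rows[f"POS_{chr(65 + i)}"] = nb(pos_ladder[i] * lane, design.technical_dispersion)
    for i in range(design.n_negative):
        rows[f"NEG_{chr(65 + i)}"] = nb(
            np.full(len(samples), 8.0) * lane, design.technical_dispersion
        )
    hk_base = np.exp(rng.uniform(np.log(300), np.log(3_000), design.n_housekeeping))
    for i in range(design.n_housekeeping):
        rows[f"HK_{i:02d}"] = nb(hk_base[i] * lane * content)

    all_probes = list(rows)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples).loc[all_probes]
    probe_class = pd.Series(
        ["endogenous"] * len(probes)
        + ["positive"] * design.n_positive
        + ["negative"] * design.n_negative
        + ["housekeeping"] * design.n_housekeeping,
        index=all_probes,
    )
    table = CountTable(
        counts,
        probe_class,
        pd.Series(conds, index=samples),
        pd.Series(reps, index=samples),
    )
    return table, truth


# ---------------------------------------------------------------------------
# recovery scoring


def score_recovery(
    called: Sequence[PutativeEnhancer],
    planted: Sequence[PlantedEnhancer],
) -> dict[str, float]:
    """Sensitivity and false-discovery rate of calls against planted valleys.

    A call matches a planted enhancer when the two valleys share >= 1 bp.
    """
    matched_truth = set()
    false_calls = 0
    for c in called:
        hit = False
        for i, t in enumerate(planted):
            if (
                t.valley.chrom == c.valley.chrom
                and t.valley.start < c.valley.end
                and c.valley.start < t.valley.end
            ):
                matched_truth.add(i)
                hit = True
        if not hit:
            false_calls += 1
    sens = len(matched_truth) / len(planted) if planted else float("nan")
    fdr = false_calls / len(called) if called else 0.0
    return {
        "sensitivity": sens,
        "fdr": fdr,
        "n_called": len(called),
        "n_planted": len(planted),
    }
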