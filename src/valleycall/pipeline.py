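"""End-to-end orchestration: configuration, run directory, manifest, report.

``run_all`` executes the stages in dependency order — simulate (optional)
-> enhancer calling per condition -> condition comparison -> profiles and
clustering -> motif enrichment -> conservation -> expression response —
writing every artefact into a run directory together with a MANIFEST
listing each output file with its SHA-256, the seed and the config hash.
Reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import conservation as cons
from . import enhancers as enh
from . import expression as expr
from . import motifs as mot
from . import profiles as prof
from . import simulate as sim
from .intervals import (
    GenomicInterval,
    read_annotation,
    read_bed,
    read_bedgraph,
    write_bed,
    write_bedgraph,
    write_gff3,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the published analysis
    values where one exists (3 kb inner gap, +/-5 kb profile window, k=5,
    1000 shuffles, PWM p=1e-4, e<=0.05, 8 bp words / 300 bp windows /
    7-of-9 species, alpha=0.05)."""

    seed: int = 7
    out_dir: str = "run"
    simulate: bool = True
    # explicit inputs (used when simulate is False)
    ac_bed: dict = field(default_factory=dict)       # condition -> path
    me3_bed: dict = field(default_factory=dict)      # condition -> path
    ac_track: dict = field(default_factory=dict)     # condition -> path
    genes_path: str | None = None
    genes_format: str = "gff3"
    orthologs_fasta: str | None = None
    counts_tsv: str | None = None
    pwms_path: str | None = None
    # parameters
    max_inner_gap: int = enh.DEFAULT_MAX_INNER_GAP
    promoter_up: int = 2000
    promoter_down: int = 500
    profile_window: int = prof.DEFAULT_WINDOW
    tss_window: int = 2000
    bin_size: int = prof.DEFAULT_BIN_SIZE
    k_clusters: int = prof.DEFAULT_K
    pwm_p: float = 1e-4
    n_shuffles: int = 1000
    e_threshold: float = 0.05
    cons_word: int = cons.DEFAULT_WORD
    cons_window: int = cons.DEFAULT_WINDOW
    cons_step: int = cons.DEFAULT_STEP
    cons_min_shared: int = cons.DEFAULT_MIN_SHARED
    cons_min_species: int = cons.DEFAULT_MIN_SPECIES
    threshold_preset: str = expr.DEFAULT_PRESET
    alpha: float = expr.DEFAULT_ALPHA
    # simulation scale
    sim_chrom_length: int = 1_000_000
    sim_n_enhancers: int = 40
    sim_jitter_sd: float = 30.0
    sim_motif_fraction: float = 0.6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        # out_dir is where the run lands, not part of its identity
        data = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        data = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_fasta(seqs: dict[str, str], path: Path, descriptions: dict | None = None) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description=(descriptions or {}).get(name, ""))
        for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _enhancer_bed_name(e: enh.PutativeEnhancer) -> GenomicInterval:
    name = f"{e.gene_id or 'NA'}|{e.context or 'NA'}|{e.condition or 'NA'}"
    return GenomicInterval(
        e.valley.chrom, e.valley.start, e.valley.end, ".", name, float(e.valley.length)
    )


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    config.to_yaml(out / "config.yaml")
    rng_seed = config.seed

    truth = None
    pwms = (
        mot.read_jaspar(config.pwms_path)
        if config.pwms_path
        else [mot.ap1_fixture()]
    )
    ap1 = pwms[0]

    # ---- stage: inputs ----------------------------------------------------
    if config.simulate:
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        truth = sim.generate_genome(
            rng_seed, n_chrom=1, chrom_length=config.sim_chrom_length
        )
        planted = sim.plant_enhancers(
            truth,
            seed=rng_seed + 1,
            n_per_condition=config.sim_n_enhancers,
            jitter_sd=config.sim_jitter_sd,
        )
        truth = sim.plant_motifs(
            truth, ap1, fraction_fgf=config.sim_motif_fraction, seed=rng_seed + 2
        )
        orthologs = sim.make_orthologs(truth, seed=rng_seed + 3)
        counts, response_truth = sim.simulate_counts(seed=rng_seed + 4)
        truth.response = response_truth

        _write_fasta(truth.genome, inputs / "genome.fa")
        write_gff3(truth.genes, inputs / "genes.gff3")
        for cond in sim.CONDITIONS:
            write_bed(planted.ac_peaks[cond], inputs / f"H3K27ac_{cond}.bed")
            write_bed(planted.me3_peaks[cond], inputs / f"H3K27me3_{cond}.bed")
            write_bedgraph(planted.ac_tracks[cond], inputs / f"H3K27ac_{cond}.bedGraph")
            write_bedgraph(planted.me3_tracks[cond], inputs / f"H3K27me3_{cond}.bedGraph")
        _write_fasta(
            dict([(orthologs.reference_species, orthologs.reference_seq)] + orthologs.others),
            inputs / "orthologs.fa",
            descriptions={
                orthologs.reference_species: f"{orthologs.origin.chrom}:{orthologs.origin.start}-{orthologs.origin.end}"
            },
        )
        counts.to_tsv(inputs / "counts.tsv")
        with open(inputs / "truth.json", "w", newline="\n") as fh:
            json.dump(_truth_json(truth), fh, indent=1, sort_keys=True)
        ac_beds = {c: inputs / f"H3K27ac_{c}.bed" for c in sim.CONDITIONS}
        me3_beds = {c: inputs / f"H3K27me3_{c}.bed" for c in sim.CONDITIONS}
        ac_tracks = {c: planted.ac_tracks[c] for c in sim.CONDITIONS}
        genes = truth.genes
        counts_table = counts
        ortho = orthologs
        genome = truth.genome
    else:
        if not config.ac_bed or not config.me3_bed:
            raise StageError("enhancer_calling", "missing ac/me3 BED inputs")
        ac_beds = {c: Path(p) for c, p in config.ac_bed.items()}
        me3_beds = {c: Path(p) for c, p in config.me3_bed.items()}
        ac_tracks = {
            c: read_bedgraph(p) for c, p in (config.ac_track or {}).items()
        }
        genes = (
            read_annotation(config.genes_path, config.genes_format)  # type: ignore[arg-type]
            if config.genes_path
            else []
        )
        counts_table = (
            expr.CountTable.from_tsv(config.counts_tsv) if config.counts_tsv else None
        )
        ortho = (
            cons.OrthologSet.from_fasta(config.orthologs_fasta)
            if config.orthologs_fasta
            else None
        )
        genome = None

    # ---- stage: enhancer_calling -----------------------------------------
    try:
        called: dict[str, list[enh.PutativeEnhancer]] = {}
        for cond in sorted(ac_beds):
            if cond not in me3_beds:
                raise StageError("enhancer_calling", f"no H3K27me3 BED for {cond}")
            called[cond] = enh.call_enhancers(
                read_bed(ac_beds[cond]),
                read_bed(me3_beds[cond]),
                genes,
                config.max_inner_gap,
                condition=cond,
            )
            write_bed(
                [_enhancer_bed_name(e) for e in called[cond]],
                out / f"enhancers_{cond}.bed",
            )
            dist = enh.context_distribution(called[cond]) if genes else None
            if dist is not None:
                pd.Series(dist).to_csv(
                    out / f"context_{cond}.tsv", sep="\t", header=["count"]
                )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("enhancer_calling", str(exc)) from exc

    # ---- stage: comparison ------------------------------------------------
    conds = sorted(called)
    comparison = None
    if len(conds) == 2:
        comparison = enh.compare_conditions(called[conds[0]], called[conds[1]])
        rows = [
            {"set": f"unique_{conds[0]}", "count": len(comparison.unique_a)},
            {"set": f"unique_{conds[1]}", "count": len(comparison.unique_b)},
            {"set": "common", "count": len(comparison.common)},
        ]
        pd.DataFrame(rows).to_csv(out / "comparison.tsv", sep="\t", index=False)

    # ---- stage: profiles --------------------------------------------------
    cluster_info = {}
    try:
        for cond, track in sorted(ac_tracks.items()):
            tss_anchors = [g.tss for g in genes if g.body.chrom in track.chroms]
            if tss_anchors:
                m = prof.extract_matrix(
                    track, tss_anchors, config.tss_window, config.bin_size
                )
                curve = prof.metaprofile(m)
                pd.DataFrame(
                    {
                        "bin_start": np.arange(-config.tss_window, config.tss_window, config.bin_size),
                        "mean_density": curve,
                    }
                ).to_csv(out / f"tss_metaprofile_{cond}.tsv", sep="\t", index=False)
        # AP1-centred H3K27ac matrix in the FGF-like condition
        if genome is not None and "FGF" in ac_tracks:
            anchors = []
            thr = mot.score_threshold(ap1, config.pwm_p)
            for e in called.get("FGF", []):
                seq = genome[e.valley.chrom][e.valley.start : e.valley.end]
                for hit in mot.scan(seq, ap1, thr, chrom=e.valley.chrom, offset=e.valley.start):
                    c = hit.location.midpoint
                    anchors.append(
                        GenomicInterval(hit.location.chrom, c, c + 1, hit.strand)
                    )
            if anchors:
                m = prof.extract_matrix(
                    ac_tracks["FGF"], anchors, config.profile_window, config.bin_size
                )
                np.savetxt(out / "ap1_matrix_FGF.tsv", m.values, delimiter="\t", fmt="%.6g")
                if len(anchors) >= config.k_clusters:
                    res = prof.cluster_profiles(m, config.k_clusters, seed=config.seed)
                    pd.DataFrame(
                        {
                            "chrom": [a.chrom for a in anchors],
                            "pos": [a.start for a in anchors],
                            "cluster": res.labels,
                        }
                    ).to_csv(out / "ap1_clusters_FGF.tsv", sep="\t", index=False)
                    cluster_info = {
                        "k": res.k,
                        "inertia": res.inertia,
                        "sizes": res.sizes().tolist(),
                    }
    except Exception as exc:
        raise StageError("signal_profiles", str(exc)) from exc

    # ---- stage: motifs ----------------------------------------------------
    motif_table = None
    if genome is not None and {"CNT", "FGF"}.issubset(called):
        try:
            seqs = {
                cond: [
                    genome[e.valley.chrom][e.valley.start : e.valley.end]
                    for e in called[cond]
                ]
                for cond in ("FGF", "CNT")
            }
            motif_table = mot.differential_motif_enrichment(
                seqs["FGF"],
                seqs["CNT"],
                pwms,
                n_shuffles=config.n_shuffles,
                seed=config.seed,
                e_threshold=config.e_threshold,
            )
            motif_table.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError("motif_analysis", str(exc)) from exc

    # ---- stage: conservation ----------------------------------------------
    blocks = []
    if ortho is not None:
        try:
            blocks = cons.find_conserved_blocks(
                ortho,
                word=config.cons_word,
                window=config.cons_window,
                step=config.cons_step,
                min_shared=config.cons_min_shared,
                min_species=config.cons_min_species,
            )
            write_bed(
                [
                    GenomicInterval(
                        b.window.chrom,
                        b.window.start,
                        b.window.end,
                        ".",
                        ",".join(sorted(b.supporting_species)),
                        float(len(b.supporting_species)),
                    )
                    for b in blocks
                ],
                out / "conserved_blocks.bed",
            )
            all_called = [e for cond in conds for e in called[cond]]
            cons.annotate_blocks(blocks, all_called).to_csv(
                out / "enhancer_conservation.tsv", sep="\t", index=False
            )
        except Exception as exc:
            raise StageError("conservation", str(exc)) from exc

    # ---- stage: expression ------------------------------------------------
    classification = None
    if counts_table is not None:
        try:
            normed = expr.normalize(counts_table)
            plain = expr.respond(
                normed, "FGF", "CNT", preset=config.threshold_preset, alpha=config.alpha
            )
            chx = expr.respond(
                normed, "FGF_CHX", "CHX", preset=config.threshold_preset, alpha=config.alpha
            )
            plain.table.to_csv(out / "response_FGF_vs_CNT.tsv", sep="\t")
            chx.table.to_csv(out / "response_FGFCHX_vs_CHX.tsv", sep="\t")
            classification = expr.classify_direct(plain, chx)
            classification.classes.to_frame("target_class").to_csv(
                out / "target_classification.tsv", sep="\t"
            )
            with open(out / "venn_counts.json", "w", newline="\n") as fh:
                json.dump(expr.venn_overlap(plain, chx), fh, indent=1, sort_keys=True)
        except Exception as exc:
            raise StageError("expression_response", str(exc)) from exc

    # ---- report and manifest ----------------------------------------------
    report = _report(
        config, called, comparison, cluster_info, motif_table, blocks, classification, truth
    )
    (out / "report.md").write_text(report, newline="\n")

    manifest_lines = [f"# seed={config.seed} config={config.digest()}"]
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "MANIFEST":
            manifest_lines.append(f"{_sha256(f)}  {f.relative_to(out).as_posix()}")
    (out / "MANIFEST").write_text("\n".join(manifest_lines) + "\n", newline="\n")
    log.info("run complete in %.1f s -> %s", time.time() - t0, out)
    return out


def _truth_json(truth: sim.SyntheticTruth) -> dict:
    return {
        "seed": truth.seed,
        "genes": [g.gene_id for g in truth.genes],
        "enhancers": [
            {
                "chrom": e.valley.chrom,
                "start": e.valley.start,
                "end": e.valley.end,
                "target_gene": e.target_gene,
                "conditions": list(e.conditions),
                "has_ap1": e.has_ap1,
            }
            for e in truth.enhancers
        ],
        "motif_sites": [
            {"chrom": m.chrom, "start": m.start, "end": m.end, "strand": m.strand}
            for m in truth.motif_sites
        ],
        "conserved_blocks": [
            {"chrom": b.chrom, "start": b.start, "end": b.end}
            for b in truth.conserved_blocks
        ],
        "response": truth.response.to_dict() if truth.response is not None else {},
    }


def _report(config, called, comparison, cluster_info, motif_table, blocks, classification, truth) -> str:
    lines = ["# valleycall run report", "", f"config hash: {config.digest()}", f"seed: {config.seed}", ""]
    lines.append("## Enhancer calling")
    for cond, es in sorted(called.items()):
        lines.append(f"- {cond}: {len(es)} putative enhancers")
    if comparison is not None:
        c = comparison.counts
        lines.append(
            f"- comparison: {c['unique_a']} unique / {c['unique_b']} unique / {c['common']} common"
        )
    if truth is not None:
        lines.append("")
        lines.append("## Recovery vs planted truth")
        for cond, es in sorted(called.items()):
            sc = sim.score_recovery(es, truth.enhancers_of(cond))
            lines.append(
                f"- {cond}: sensitivity {sc['sensitivity']:.3f}, FDR {sc['fdr']:.3f} "
                f"({sc['n_called']} called / {sc['n_planted']} planted)"
            )
    if cluster_info:
        lines.append("")
        lines.append("## AP1-centred clustering")
        lines.append(
            f"- k={cluster_info['k']}, inertia {cluster_info['inertia']:.4g}, sizes {cluster_info['sizes']}"
        )
    if motif_table is not None:
        lines.append("")
        lines.append("## Differential motif enrichment (FGF vs CNT)")
        for _, row in motif_table.iterrows():
            lines.append(
                f"- {row['pwm']}: stat {row['observed_stat']:.3f}, p {row['p_value']:.4g}, "
                f"e {row['e_value']:.4g}{' *' if row['significant'] else ''}"
            )
    if blocks:
        lines.append("")
        lines.append(f"## Conservation: {len(blocks)} conserved block(s)")
    if classification is not None:
        lines.append("")
        lines.append("## Target classification")
        counts = classification.classes.value_counts().sort_index()
        for cls, n in counts.items():
            lines.append(f"- {cls}: {n}")
    lines.append("")
    return "\n".join(lines)
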