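"""End-to-end pipeline: simulate -> synteny -> density -> te -> forensics -> rate.

Stages hand off through documented TSV/FASTA/GFF3 file contracts inside the
output directory, so each stage is independently re-runnable and testable.
A machine-readable manifest (seed, parameters, per-stage output checksums)
is written at the end; reruns with identical config and seed produce
byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, density, forensics, io, rates, synteny, te_metrics
from .errors import ConfigError, DataError
from .sim_core import SimConfig, simulate_divergent_pair, terminal_inversion_plan
from .synthetic_data import write_genome_pair

log = logging.getLogger("gsred")

STAGES = ("simulate", "synteny", "density", "te", "forensics", "rate")


@dataclass
class PipelineConfig:
    outdir: Path = Path("gsred_out")
    seed: int = 0
    log_level: str = "INFO"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # simulate
    sim_overrides: dict = field(default_factory=dict)
    inversion_chrom: int = 0
    inversion_start_fraction: float = 0.52
    divergence: float = 0.02
    terminus_divergence: float = 0.0
    n_markers: int = 80
    # external inputs (used when the simulate stage is disabled)
    inputs: dict = field(default_factory=dict)
    # synteny
    max_gap: int = 5
    min_pairs: int = 4
    max_pairs_per_block: Optional[int] = 8
    skip_tolerance: int = 0
    # density
    n_partitions: int = 500
    marey_window: int = 50_000
    # forensics
    min_repeat_len: int = 50
    max_endpoint_distance: int = 100
    long_threshold: int = 1_000
    min_identity: float = 1.0
    # rate
    rate_n_generations: Optional[int] = None
    rate_variant: str = "compound"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: pipeline config must be a mapping")
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"{path}: unknown config key {key!r}")
            if key == "stages":
                cfg.stages.update(val)
            else:
                setattr(cfg, key, val)
        cfg.outdir = Path(cfg.outdir)
        return cfg

    def sim_config(self) -> SimConfig:
        return SimConfig(rng_seed=self.seed, **self.sim_overrides)


def _require(path: Path, stage: str) -> Path:
    if not Path(path).exists():
        raise DataError(f"stage {stage}: missing contract file {path}")
    return Path(path)


def _paths(cfg: PipelineConfig) -> dict:
    data = Path(cfg.outdir) / "data"
    named = dict(
        fasta_I=data / "genome_I.fasta",
        fasta_D=data / "genome_D.fasta",
        gff_I=data / "genome_I.gff3",
        gff_D=data / "genome_D.gff3",
        marker_map=data / "marker_map.tsv",
        alignment_blocks=data / "alignment_blocks.tsv",
    )
    for key, val in cfg.inputs.items():
        named[key] = Path(val)
    return named


def _chrom_pairs(ann_I: pd.DataFrame, ann_D: pd.DataFrame) -> list[tuple[str, str]]:
    """Match chromosomes across genomes by shared prefix (chrNN_I ~ chrNN_D)."""

    def stem(name: str) -> str:
        return name.rsplit("_", 1)[0]

    by_stem_i = {stem(c): c for c in ann_I["chrom"].unique()}
    by_stem_d = {stem(c): c for c in ann_D["chrom"].unique()}
    return [(by_stem_i[s], by_stem_d[s]) for s in sorted(set(by_stem_i) & set(by_stem_d))]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    sim_cfg = cfg.sim_config()
    plan = terminal_inversion_plan(sim_cfg, cfg.inversion_chrom, cfg.inversion_start_fraction)
    pair = simulate_divergent_pair(sim_cfg, plan)
    bundle = write_genome_pair(
        pair,
        Path(cfg.outdir) / "data",
        divergence=cfg.divergence,
        terminus_divergence=cfg.terminus_divergence,
        n_markers=cfg.n_markers,
    )
    log.info(
        "simulate: %d chromosome(s), %d generations, %d truth events",
        sim_cfg.n_chromosomes,
        sim_cfg.n_generations,
        sum(len(c.log) for g in (pair.genome_I, pair.genome_D) for c in g),
    )
    return [
        bundle.fasta_I, bundle.fasta_D, bundle.gff_I, bundle.gff_D,
        bundle.marker_map, bundle.alignment_blocks, bundle.truth_events,
        bundle.ortholog_truth,
    ]


def stage_synteny(cfg: PipelineConfig) -> list[Path]:
    paths = _paths(cfg)
    ann_I = io.read_annotation(_require(paths["gff_I"], "synteny"))
    ann_D = io.read_annotation(_require(paths["gff_D"], "synteny"))
    out = Path(cfg.outdir) / "synteny"
    out.mkdir(parents=True, exist_ok=True)
    all_blocks, inv_rows = [], []
    for chrom_i, chrom_d in _chrom_pairs(ann_I, ann_D):
        genes_i = ann_I[(ann_I["chrom"] == chrom_i) & (ann_I["kind"] == "gene")]
        genes_d = ann_D[(ann_D["chrom"] == chrom_d) & (ann_D["kind"] == "gene")]
        pairs = synteny.find_homolog_pairs(genes_i, genes_d)
        blocks = synteny.chain_synteny_blocks(
            pairs,
            max_gap=cfg.max_gap,
            min_pairs=cfg.min_pairs,
            chrom_I=chrom_i,
            chrom_D=chrom_d,
            max_pairs_per_block=cfg.max_pairs_per_block,
        )
        all_blocks.extend(blocks)
        for region in synteny.detect_inversions(blocks, cfg.skip_tolerance):
            inv_rows.append(
                dict(
                    chrom_I=region["chrom_I"], chrom_D=region["chrom_D"],
                    start_I=region["span_I"][0], end_I=region["span_I"][1],
                    start_D=region["span_D"][0], end_D=region["span_D"][1],
                    n_blocks=region["n_blocks"],
                )
            )
        log.info("synteny: %s~%s %d pairs -> %d blocks", chrom_i, chrom_d,
                 len(pairs), len(blocks))
    inversions = pd.DataFrame(
        inv_rows,
        columns=["chrom_I", "chrom_D", "start_I", "end_I", "start_D", "end_D", "n_blocks"],
    )
    regions = [
        dict(chrom_I=r.chrom_I, chrom_D=r.chrom_D, span_I=(r.start_I, r.end_I),
             span_D=(r.start_D, r.end_D))
        for r in inversions.itertuples()
    ]
    summary = synteny.region_ratio_summary(all_blocks, regions)
    io.write_tsv(synteny.blocks_to_frame(all_blocks), out / "blocks.tsv")
    io.write_tsv(inversions, out / "inversions.tsv")
    io.write_tsv(summary.per_block, out / "per_block_ratios.tsv")
    io.write_tsv(
        pd.DataFrame(
            [dict(category="inverted", ratio=summary.inverted_ratio),
             dict(category="non_inverted", ratio=summary.non_inverted_ratio)]
        ),
        out / "ratio_summary.tsv",
    )
    return [out / "blocks.tsv", out / "inversions.tsv", out / "per_block_ratios.tsv",
            out / "ratio_summary.tsv"]


def _lengths_from_fasta(path) -> dict[str, int]:
    return {name: len(seq) for name, seq in io.read_fasta(path).items()}


def stage_density(cfg: PipelineConfig) -> list[Path]:
    paths = _paths(cfg)
    out = Path(cfg.outdir) / "density"
    out.mkdir(parents=True, exist_ok=True)
    ann_I = io.read_annotation(_require(paths["gff_I"], "density"))
    ann_D = io.read_annotation(_require(paths["gff_D"], "density"))
    len_I = _lengths_from_fasta(_require(paths["fasta_I"], "density"))
    len_D = _lengths_from_fasta(_require(paths["fasta_D"], "density"))
    track_frames, diff_rows, score_rows = [], [], []
    for chrom_i, chrom_d in _chrom_pairs(ann_I, ann_D):
        t_i = density.partition_gene_density(ann_I, chrom_i, len_I[chrom_i], cfg.n_partitions)
        t_d = density.partition_gene_density(ann_D, chrom_d, len_D[chrom_d], cfg.n_partitions)
        track_frames += [t_i.to_frame().assign(genome="I"), t_d.to_frame().assign(genome="D")]
        diff = density.density_difference(t_i, t_d)
        diff_rows.append(
            pd.DataFrame(
                dict(chrom_I=chrom_i, chrom_D=chrom_d,
                     partition=np.arange(cfg.n_partitions), difference=diff)
            )
        )
        score_rows += [
            dict(genome="I", chrom=chrom_i,
                 disruption=density.gradient_disruption_score(t_i)),
            dict(genome="D", chrom=chrom_d,
                 disruption=density.gradient_disruption_score(t_d)),
        ]
    io.write_tsv(pd.concat(track_frames, ignore_index=True), out / "density_tracks.tsv")
    io.write_tsv(pd.concat(diff_rows, ignore_index=True), out / "density_difference.tsv")
    io.write_tsv(pd.DataFrame(score_rows), out / "disruption_scores.tsv")
    outputs = [out / "density_tracks.tsv", out / "density_difference.tsv",
               out / "disruption_scores.tsv"]
    marker_path = paths["marker_map"]
    if Path(marker_path).exists():
        markers = io.read_tsv(marker_path)
        profiles = [
            density.marey_recombination_profile(markers, cfg.marey_window, chrom)
            .table.assign(chrom=chrom)
            for chrom in markers["chrom"].unique()
        ]
        io.write_tsv(pd.concat(profiles, ignore_index=True), out / "marey_profile.tsv")
        outputs.append(out / "marey_profile.tsv")
    return outputs


def _load_blocks(cfg: PipelineConfig) -> list[synteny.SyntenyBlock]:
    path = _require(Path(cfg.outdir) / "synteny" / "blocks.tsv", "te")
    df = io.read_tsv(path)
    return [
        synteny.SyntenyBlock(
            r.chrom_I, r.chrom_D, (int(r.start_I), int(r.end_I)),
            (int(r.start_D), int(r.end_D)), int(r.orientation), int(r.n_pairs),
        )
        for r in df.itertuples()
    ]


def _load_inverted_regions(cfg: PipelineConfig, stage: str) -> list[dict]:
    path = _require(Path(cfg.outdir) / "synteny" / "inversions.tsv", stage)
    df = io.read_tsv(path)
    return [
        dict(chrom_I=r.chrom_I, chrom_D=r.chrom_D,
             span_I=(int(r.start_I), int(r.end_I)),
             span_D=(int(r.start_D), int(r.end_D)))
        for r in df.itertuples()
    ]


def stage_te(cfg: PipelineConfig) -> list[Path]:
    paths = _paths(cfg)
    out = Path(cfg.outdir) / "te"
    out.mkdir(parents=True, exist_ok=True)
    ann_I = io.read_annotation(_require(paths["gff_I"], "te"))
    ann_D = io.read_annotation(_require(paths["gff_D"], "te"))
    blocks = _load_blocks(cfg)
    regions = _load_inverted_regions(cfg, "te")
    stats = te_metrics.block_te_stats(blocks, ann_I, ann_D)
    io.write_tsv(stats, out / "block_te_stats.tsv")
    corr_rows = []
    for chrom in stats["chrom_I"].unique():
        sub = stats[stats["chrom_I"] == chrom]
        try:
            corr_rows.append(
                dict(chrom_I=chrom,
                     r2_te=te_metrics.ratio_correlation(sub, "te"),
                     r2_gene=te_metrics.ratio_correlation(sub, "gene"))
            )
        except DataError:
            continue
    io.write_tsv(
        pd.DataFrame(corr_rows, columns=["chrom_I", "r2_te", "r2_gene"]),
        out / "ratio_correlations.tsv",
    )
    inv_I = [(r["chrom_I"], *r["span_I"]) for r in regions]
    inv_D = [(r["chrom_D"], *r["span_D"]) for r in regions]
    chroms_I = list(ann_I["chrom"].unique())
    chroms_D = list(ann_D["chrom"].unique())
    len_I = {c: int(ann_I[ann_I["chrom"] == c]["end"].max()) for c in chroms_I}
    len_D = {c: int(ann_D[ann_D["chrom"] == c]["end"].max()) for c in chroms_D}
    non_I = _complement_regions(inv_I, len_I)
    non_D = _complement_regions(inv_D, len_D)
    comp = te_metrics.composition_table(
        ann_I, ann_D,
        {"inverted": {"I": inv_I, "D": inv_D},
         "non_inverted": {"I": non_I, "D": non_D}},
    )
    io.write_tsv(comp, out / "composition.tsv")
    return [out / "block_te_stats.tsv", out / "ratio_correlations.tsv",
            out / "composition.tsv"]


def _complement_regions(regions, lengths: dict[str, int]):
    by_chrom: dict[str, list] = {c: [] for c in lengths}
    for chrom, s, e in regions:
        if chrom in by_chrom:
            by_chrom[chrom].append((s, e))
    out = []
    for chrom, spans in by_chrom.items():
        cursor = 0
        for s, e in sorted(spans):
            if s > cursor:
                out.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < lengths[chrom]:
            out.append((chrom, cursor, lengths[chrom]))
    return out


def stage_forensics(cfg: PipelineConfig) -> list[Path]:
    paths = _paths(cfg)
    out = Path(cfg.outdir) / "forensics"
    out.mkdir(parents=True, exist_ok=True)
    blocks = io.read_tsv(_require(paths["alignment_blocks"], "forensics"))
    seqs = {tag: io.read_fasta(_require(paths[f"fasta_{tag}"], "forensics"))
            for tag in ("I", "D")}
    anns = {tag: io.read_annotation(paths[f"gff_{tag}"]) for tag in ("I", "D")}
    lengths = {tag: {c: len(s) for c, s in seqs[tag].items()} for tag in ("I", "D")}
    segments = forensics.extract_unaligned_segments(blocks, lengths)
    fcfg = forensics.FlankingRepeatConfig(cfg.min_repeat_len, cfg.max_endpoint_distance)
    outputs = []
    for tag in ("I", "D"):
        seg = forensics.classify_segments(segments[tag], anns[tag], fcfg)
        seg = forensics.segment_components(seg, anns[tag])
        io.write_tsv(seg, out / f"unaligned_segments_{tag}.tsv")
        io.write_tsv(forensics.bin_unaligned_lengths(seg), out / f"length_bins_{tag}.tsv")
        long_seg = seg[seg["length"] >= cfg.long_threshold]
        io.write_tsv(
            forensics.mechanism_fraction_report(long_seg),
            out / f"mechanism_fractions_{tag}.tsv",
        )
        log.info("forensics %s: %d segments (%d long)", tag, len(seg), len(long_seg))
        outputs += [out / f"unaligned_segments_{tag}.tsv", out / f"length_bins_{tag}.tsv",
                    out / f"mechanism_fractions_{tag}.tsv"]
    try:
        regions_by_tag = {
            "I": [(r["chrom_I"], *r["span_I"]) for r in _load_inverted_regions(cfg, "forensics")],
            "D": [(r["chrom_D"], *r["span_D"]) for r in _load_inverted_regions(cfg, "forensics")],
        }
    except DataError:
        regions_by_tag = {"I": [], "D": []}
    inv_rows = []
    for tag in ("I", "D"):
        regions = regions_by_tag[tag] or [
            (c, 0, L) for c, L in lengths[tag].items()
        ]
        inv = forensics.ltr_inventory(seqs[tag], anns[tag], regions, cfg.min_identity)
        inv.insert(0, "genome", tag)
        inv_rows.append(inv)
    io.write_tsv(pd.concat(inv_rows, ignore_index=True), out / "ltr_inventory.tsv")
    outputs.append(out / "ltr_inventory.tsv")
    return outputs


def stage_rate(cfg: PipelineConfig) -> list[Path]:
    out = Path(cfg.outdir) / "rate"
    out.mkdir(parents=True, exist_ok=True)
    regions = _load_inverted_regions(cfg, "rate")
    n = cfg.rate_n_generations
    if n is None:
        n = cfg.sim_config().n_generations
    pairs = [
        (r["span_I"][1] - r["span_I"][0], r["span_D"][1] - r["span_D"][0])
        for r in regions
    ]
    labels = [f"{r['chrom_I']}~{r['chrom_D']}" for r in regions]
    if pairs:
        report = rates.per_region_rates(pairs, n, cfg.rate_variant, labels)
    else:
        report = pd.DataFrame(
            columns=["region", "a", "b", "n", "variant", "x",
                     "bases_per_generation", "is_growth"]
        )
    io.write_tsv(report, out / "rate_report.tsv")
    return [out / "rate_report.tsv"]


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "synteny": stage_synteny,
    "density": stage_density,
    "te": stage_te,
    "forensics": stage_forensics,
    "rate": stage_rate,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run enabled stages in order and write the run manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(
        package="gsred",
        version=__version__,
        seed=cfg.seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        parameters={
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(cfg).items()
            if k not in ("stages",)
        },
        stages={},
    )
    for name in STAGES:
        if not cfg.stages.get(name, True):
            manifest["stages"][name] = dict(status="skipped")
            log.info("stage %s: skipped", name)
            continue
        outputs = STAGE_FUNCS[name](cfg)
        manifest["stages"][name] = dict(
            status="complete",
            outputs={str(Path(p).relative_to(outdir)): io.sha256_file(p) for p in outputs},
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
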