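"""Shared fixtures: small deterministic simulations and replicate summaries.

The heavyweight fixtures are session-scoped so the replicate set backing the
distributional checks (overall ratios, R-squared contrast, block-ratio
gradient, mechanism fractions) is simulated once and shared.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from gsred import density, io, synteny, te_metrics, forensics
from gsred.sim_core import (
    SimConfig,
    simulate_divergent_pair,
    surviving_unequal_events,
    terminal_inversion_plan,
)
from gsred.synthetic_data import alignment_blocks, fixture_pair, write_genome_pair

N_REPLICATES = 30


@pytest.fixture(scope="session")
def tiny_pair():
    return fixture_pair("tiny-inversion")


@pytest.fixture(scope="session")
def tiny_bundle(tiny_pair, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_bundle")
    return write_genome_pair(tiny_pair, out)


def _summarise_seed(seed: int) -> dict:
    cfg = SimConfig(rng_seed=seed)
    pair = simulate_divergent_pair(cfg, terminal_inversion_plan(cfg))
    ann_I = io.features_to_frame(pair.genome_I)
    ann_D = io.features_to_frame(pair.genome_D)
    pairs = synteny.find_homolog_pairs(
        ann_I[ann_I.kind == "gene"], ann_D[ann_D.kind == "gene"]
    )
    blocks = synteny.chain_synteny_blocks(
        pairs, chrom_I="chr01_I", chrom_D="chr01_D", max_pairs_per_block=10
    )
    regions = synteny.detect_inversions(blocks)
    summary = synteny.region_ratio_summary(blocks, regions)
    stats = te_metrics.block_te_stats(blocks, ann_I, ann_D)
    r2_te = te_metrics.ratio_correlation(stats, "te")
    r2_gene = te_metrics.ratio_correlation(stats, "gene")

    # density-difference enrichment inside the detected inversion (pooled
    # later; partitions coarse enough to hold several genes at desk scale)
    ci, cd = pair.genome_I[0], pair.genome_D[0]
    t_i = density.partition_gene_density(ann_I, ci.name, ci.length, 50)
    t_d = density.partition_gene_density(ann_D, cd.name, cd.length, 50)
    diff = density.density_difference(t_i, t_d)
    enr = dict(enr_a=0, enr_b=0, enr_c=0, enr_d=0)
    if regions:
        span_i = regions[0]["span_I"]
        mids = (t_i.starts + t_i.ends) // 2
        inside = (mids >= span_i[0]) & (mids < span_i[1])
        top = np.abs(diff) >= np.quantile(np.abs(diff), 0.80)
        enr = dict(
            enr_a=int((top & inside).sum()), enr_b=int((top & ~inside).sum()),
            enr_c=int((~top & inside).sum()), enr_d=int((~top & ~inside).sum()),
        )

    per_block = summary.per_block
    inv_blocks = per_block[per_block.inverted].sort_values("start_D")
    rho = np.nan
    if len(inv_blocks) >= 4:
        rho = spearmanr(np.arange(len(inv_blocks)), inv_blocks.size_ratio).statistic

    ab = alignment_blocks(pair)
    lengths = {
        "I": {c.name: c.length for c in pair.genome_I},
        "D": {c.name: c.length for c in pair.genome_D},
    }
    segs = forensics.extract_unaligned_segments(ab, lengths)
    split = {tag: forensics.short_long_split(segs[tag]) for tag in ("I", "D")}
    return dict(
        seed=seed,
        inverted_ratio=summary.inverted_ratio,
        non_inverted_ratio=summary.non_inverted_ratio,
        r2_te=r2_te,
        r2_gene=r2_gene,
        spearman=rho,
        short_bp_diff=abs(split["I"]["short_bp"] - split["D"]["short_bp"]),
        long_bp_diff=abs(split["I"]["long_bp"] - split["D"]["long_bp"]),
        **enr,
    )


@pytest.fixture(scope="session")
def replicate_stats() -> pd.DataFrame:
    """Default study conditions, one terminal inversion, N_REPLICATES seeds."""
    return pd.DataFrame([_summarise_seed(seed) for seed in range(N_REPLICATES)])
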