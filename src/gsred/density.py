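"""Gene-density partition tracks, density differences, and Marey profiles.

Each chromosome is cut into ``n_partitions`` equal partitions (the division
remainder is folded into the final partition); density is expressed as genes
per 100 kb of the true partition length, so the irregular last partition
introduces no bias. Genes are assigned to the partition containing their
midpoint. Partition pairs between two genomes are matched by index even when
chromosome lengths differ, mirroring how paired-partition density
differences are taken between related genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ConfigError, DataError


@dataclass
class DensityTrack:
    chrom: str
    n_partitions: int
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray
    densities: np.ndarray  # genes per 100 kb

    @property
    def partition_lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                chrom=self.chrom,
                partition=np.arange(self.n_partitions),
                start=self.starts,
                end=self.ends,
                gene_count=self.counts,
                density=self.densities,
            )
        )


def partition_gene_density(
    annotation: pd.DataFrame,
    chromosome: str,
    chrom_length: int,
    n_partitions: int = 500,
) -> DensityTrack:
    """Per-partition gene density (genes per 100 kb) for one chromosome."""
    if chrom_length < n_partitions:
        raise ConfigError(
            f"chromosome length {chrom_length} shorter than {n_partitions} partitions"
        )
    base = chrom_length // n_partitions
    starts = np.arange(n_partitions, dtype=np.int64) * base
    ends = starts + base
    ends[-1] = chrom_length
    genes = annotation[(annotation["kind"] == "gene") & (annotation["chrom"] == chromosome)]
    mids = ((genes["start"].to_numpy() + genes["end"].to_numpy()) // 2).astype(np.int64)
    mids = mids[(mids >= 0) & (mids < chrom_length)]
    idx = np.minimum(mids // base, n_partitions - 1)
    counts = np.bincount(idx, minlength=n_partitions).astype(np.int64)
    lengths = (ends - starts).astype(float)
    densities = counts / lengths * 100_000.0
    return DensityTrack(chromosome, n_partitions, starts, ends, counts, densities)


def density_difference(track_I: DensityTrack, track_D: DensityTrack) -> np.ndarray:
    """Per-partition d_I - d_D, partitions paired by index."""
    if track_I.n_partitions != track_D.n_partitions:
        raise DataError(
            f"partition counts differ: {track_I.n_partitions} vs {track_D.n_partitions}"
        )
    return track_I.densities - track_D.densities


def gradient_disruption_score(track: DensityTrack) -> float:
    """1 - Spearman correlation against the U-shape template.

    The template is each partition midpoint's distance from the chromosome
    midpoint: an intact U-shaped chromosome correlates positively (score
    near 0), a disrupted one less so (score up to 2). A constant track has
    no defined correlation and scores 1 by convention.
    """
    if track.n_partitions < 10:
        raise ConfigError("need at least 10 partitions for a disruption score")
    mid = (track.starts + track.ends) / 2.0
    template = np.abs(mid - (track.ends[-1] / 2.0))
    if np.all(track.densities == track.densities[0]):
        return 1.0
    rho = spearmanr(track.densities, template).statistic
    if np.isnan(rho):
        return 1.0
    return float(1.0 - rho)


@dataclass
class MareyProfile:
    """Windowed Marey map: cumulative cM and local cM/Mb along a chromosome."""

    chrom: str
    table: pd.DataFrame  # win_start, win_end, cM_start, cM_end, cM_per_Mb
    violations: list = field(default_factory=list)


def marey_recombination_profile(
    markers: pd.DataFrame, window: int = 50_000, chromosome: Optional[str] = None
) -> MareyProfile:
    """Local recombination rate from marker tables (bp, cumulative cM).

    Markers are sorted by physical position; duplicate positions are a data
    error (offenders listed), and decreases in cM are flagged as violations
    but tolerated. The local rate is the finite-difference slope of
    (linearly interpolated) cumulative cM over fixed windows.
    """
    m = markers
    if chromosome is not None:
        m = m[m["chrom"] == chromosome]
    elif m["chrom"].nunique() > 1:
        raise DataError("marey profile is per-chromosome; pass `chromosome`")
    if len(m) < 2:
        raise DataError("need at least 2 markers")
    chrom = str(m["chrom"].iloc[0])
    m = m.sort_values("position_bp", kind="stable")
    pos = m["position_bp"].to_numpy(dtype=float)
    cm = m["cM"].to_numpy(dtype=float)
    dup = m["position_bp"][m["position_bp"].duplicated()].tolist()
    if dup:
        raise DataError(f"duplicated marker positions: {sorted(set(dup))}")
    violations = [
        str(m["marker_id"].iloc[k + 1]) for k in range(len(cm) - 1) if cm[k + 1] < cm[k]
    ]
    cm_mono = np.maximum.accumulate(cm)
    edges = np.arange(pos[0], pos[-1] + window, window, dtype=float)
    edges[-1] = max(edges[-1], pos[-1])
    cm_at = np.interp(edges, pos, cm_mono)
    table = pd.DataFrame(
        dict(
            win_start=edges[:-1].astype(np.int64),
            win_end=edges[1:].astype(np.int64),
            cM_start=cm_at[:-1],
            cM_end=cm_at[1:],
        )
    )
    span_mb = (table["win_end"] - table["win_start"]) / 1e6
    table["cM_per_Mb"] = (table["cM_end"] - table["cM_start"]) / span_mb
    return MareyProfile(chrom, table, violations)
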