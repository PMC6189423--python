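"""TE counts per syntenic block, composition tables, ratio correlations,
and local gene-duplication counting.

A TE is counted inside a span when its midpoint lies inside (the boundary
rule for elements straddling a span edge). Count ratios with a zero
denominator are reported as undefined (NaN) and flagged, never as zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import DataError
from .synteny import SyntenyBlock


def _midpoint_count(ann: pd.DataFrame, chrom: str, span: tuple[int, int], kind: str) -> int:
    sub = ann[(ann["chrom"] == chrom) & (ann["kind"] == kind)]
    mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
    return int(((mids >= span[0]) & (mids < span[1])).sum())


def block_te_stats(
    blocks: Sequence[SyntenyBlock], ann_I: pd.DataFrame, ann_D: pd.DataFrame
) -> pd.DataFrame:
    """Per-block TE and gene counts on both sides, count ratios, size ratio."""
    rows = []
    for bid, b in enumerate(blocks):
        te_i = _midpoint_count(ann_I, b.chrom_I, b.span_I, "te")
        te_d = _midpoint_count(ann_D, b.chrom_D, b.span_D, "te")
        g_i = _midpoint_count(ann_I, b.chrom_I, b.span_I, "gene")
        g_d = _midpoint_count(ann_D, b.chrom_D, b.span_D, "gene")
        rows.append(
            dict(
                block=bid,
                chrom_I=b.chrom_I,
                chrom_D=b.chrom_D,
                te_count_I=te_i,
                te_count_D=te_d,
                gene_count_I=g_i,
                gene_count_D=g_d,
                te_ratio=te_i / te_d if te_d else np.nan,
                gene_ratio=g_i / g_d if g_d else np.nan,
                size_ratio=b.size_ratio,
            )
        )
    return pd.DataFrame(rows)


def ratio_correlation(stats: pd.DataFrame, which: str = "te") -> float:
    """OLS R-squared between a count ratio and the block size ratio.

    Blocks with undefined ratios are excluded; fewer than 3 usable blocks is
    an error. A constant predictor has no explanatory power and returns 0.
    """
    col = {"te": "te_ratio", "gene": "gene_ratio"}[which]
    usable = stats.dropna(subset=[col, "size_ratio"])
    if len(usable) < 3:
        raise DataError(f"fewer than 3 blocks with defined {col}")
    x = usable[col].to_numpy(dtype=float)
    y = usable["size_ratio"].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return 0.0
    r = linregress(x, y).rvalue
    return float(r * r)


def composition_table(
    ann_I: pd.DataFrame,
    ann_D: pd.DataFrame,
    region_sets: dict[str, dict[str, Sequence[tuple[str, int, int]]]],
    excluded_chromosomes: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-TE-class counts and I/D ratios within labelled region sets.

    ``region_sets`` maps a label (e.g. ``inverted``) to per-genome region
    lists ``{"I": [(chrom, start, end), ...], "D": [...]}``. Elements are
    assigned by midpoint; excluded chromosomes are dropped entirely.
    """
    excluded = set(excluded_chromosomes)
    rows = []
    for label, sides in region_sets.items():
        counts = {}
        for side, ann in (("I", ann_I), ("D", ann_D)):
            tes = ann[ann["kind"] == "te"]
            mids = (tes["start"].to_numpy() + tes["end"].to_numpy()) // 2
            mask = np.zeros(len(tes), dtype=bool)
            for chrom, s, e in sides.get(side, []):
                if chrom in excluded:
                    continue
                mask |= (tes["chrom"].to_numpy() == chrom) & (mids >= s) & (mids < e)
            sel = tes[mask & ~tes["chrom"].isin(excluded).to_numpy()]
            counts[side] = sel.groupby("te_class").size()
        classes = sorted(set(counts["I"].index) | set(counts["D"].index))
        for cls in classes:
            n_i = int(counts["I"].get(cls, 0))
            n_d = int(counts["D"].get(cls, 0))
            rows.append(
                dict(
                    region_set=label,
                    te_class=cls,
                    count_I=n_i,
                    count_D=n_d,
                    ratio=n_i / n_d if n_d else np.nan,
                )
            )
    return pd.DataFrame(
        rows, columns=["region_set", "te_class", "count_I", "count_D", "ratio"]
    )


def local_gene_duplications(
    families: Sequence[str], window_size: int = 10, step: int = 1
) -> int:
    """Count genes participating in local duplications.

    A sliding window of ``window_size`` genes advances by ``step``; a gene is
    locally duplicated if any window contains another gene of its family.
    Each gene is counted once however many windows rediscover it (overlapping
    windows would otherwise multiply-count the same tandem pair). With fewer
    genes than the window, a single truncated window is used.
    """
    if window_size < 2 or step < 1:
        raise DataError("window_size must be >= 2 and step >= 1")
    n = len(families)
    flagged: set[int] = set()
    if n == 0:
        return 0
    upper = max(n - window_size + 1, 1)
    for w0 in range(0, upper, step):
        window = families[w0 : w0 + window_size]
        seen: dict[str, list[int]] = {}
        for off, fam in enumerate(window):
            seen.setdefault(fam, []).append(w0 + off)
        for fam, idxs in seen.items():
            if len(idxs) > 1:
                flagged.update(idxs)
    return len(flagged)
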