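"""Homolog pairing, collinear block chaining, inversion detection, ratios.

Chaining is a sparse dynamic program over homologous gene pairs indexed by
gene order in each genome: a block is a maximal-cardinality run of pairs
whose indices increase in both genomes (orientation +1) or increase in one
and decrease in the other (orientation -1), with inter-pair index gaps no
larger than ``max_gap`` on either side. Blocks are extracted greedily
(best chain first, pairs removed, repeat) with a fully deterministic
tie-break, standing in for DAGchainer-style chaining plus the manual
curation real studies apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class HomologPair:
    gene_I: str
    index_I: int
    span_I: tuple[int, int]
    gene_D: str
    index_D: int
    span_D: tuple[int, int]
    score: float


@dataclass
class SyntenyBlock:
    chrom_I: str
    chrom_D: str
    span_I: tuple[int, int]
    span_D: tuple[int, int]
    orientation: int
    n_pairs: int
    pairs: list[HomologPair] = field(default_factory=list, repr=False)

    @property
    def size_ratio(self) -> float:
        return size_ratio(self.span_I[1] - self.span_I[0], self.span_D[1] - self.span_D[0])


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------


def kmer_identity_scorer(seqs_I: dict, seqs_D: dict, k: int = 8) -> Callable[[str, str], float]:
    """Jaccard similarity of k-mer sets — a lightweight sequence scorer for
    use when family labels are unavailable."""

    def kmers(s: str) -> set:
        return {s[i : i + k] for i in range(0, max(len(s) - k + 1, 0))}

    cache: dict[str, set] = {}

    def score(gid_i: str, gid_d: str) -> float:
        a = cache.get(gid_i)
        if a is None:
            a = cache[gid_i] = kmers(seqs_I[gid_i])
        b = cache.get("D:" + gid_d)
        if b is None:
            b = cache["D:" + gid_d] = kmers(seqs_D[gid_d])
        if not a and not b:
            return 0.0
        return len(a & b) / len(a | b)

    return score


def find_homolog_pairs(
    genes_I: pd.DataFrame,
    genes_D: pd.DataFrame,
    scorer: Optional[Callable[[str, str], float]] = None,
    score_threshold: float = 1.0,
) -> list[HomologPair]:
    """Top-hit pairing of I-side query genes against D-side targets.

    The default scorer is exact family-label match (score 1). Each query
    keeps at most one pair; ties break to the highest score, then the
    lexicographically smallest target id. Gene frames must carry
    chrom/start/end/feature_id/family_id and be restricted to one
    chromosome pair by the caller.
    """
    gi = genes_I.sort_values("start", kind="stable").reset_index(drop=True)
    gd = genes_D.sort_values("start", kind="stable").reset_index(drop=True)
    d_index = {row.feature_id: i for i, row in enumerate(gd.itertuples())}
    pairs: list[HomologPair] = []
    if scorer is None:
        by_family: dict[str, list] = {}
        for i, row in enumerate(gd.itertuples()):
            by_family.setdefault(row.family_id, []).append(row)
        for qi, q in enumerate(gi.itertuples()):
            targets = by_family.get(q.family_id, [])
            if not targets:
                continue
            best = min(targets, key=lambda r: r.feature_id)
            pairs.append(
                HomologPair(
                    q.feature_id, qi, (q.start, q.end),
                    best.feature_id, d_index[best.feature_id],
                    (best.start, best.end), 1.0,
                )
            )
    else:
        for qi, q in enumerate(gi.itertuples()):
            best_row, best_score = None, -1.0
            for row in gd.itertuples():
                s = scorer(q.feature_id, row.feature_id)
                if s > best_score or (
                    s == best_score
                    and best_row is not None
                    and row.feature_id < best_row.feature_id
                ):
                    best_row, best_score = row, s
            if best_row is not None and best_score >= score_threshold:
                pairs.append(
                    HomologPair(
                        q.feature_id, qi, (q.start, q.end),
                        best_row.feature_id, d_index[best_row.feature_id],
                        (best_row.start, best_row.end), best_score,
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------


def _chainable(a: HomologPair, b: HomologPair, orientation: int, max_gap: int) -> bool:
    """Can chain extend from pair a to pair b (a before b along I)?"""
    if b.index_I <= a.index_I:
        return False
    if b.index_I - a.index_I - 1 > max_gap:
        return False
    if orientation > 0:
        return 0 <= b.index_D - a.index_D - 1 <= max_gap
    return 0 <= a.index_D - b.index_D - 1 <= max_gap


def _best_chain(pairs: Sequence[HomologPair], orientation: int, max_gap: int) -> list[int]:
    """Maximum-cardinality chain (as indices into ``pairs``), deterministic.

    Among equal-length chains the one with the lexicographically smallest
    sequence of (index_I, index_D)-sorted positions wins: the DP computes,
    for every pair, the longest chain starting there, and the chain is then
    rebuilt front-to-back taking the earliest feasible continuation.
    """
    order = sorted(range(len(pairs)), key=lambda k: (pairs[k].index_I, pairs[k].index_D))
    n = len(order)
    if n == 0:
        return []
    f = [1] * n
    for ai in range(n - 2, -1, -1):
        a = pairs[order[ai]]
        for bi in range(ai + 1, n):
            b = pairs[order[bi]]
            if b.index_I - a.index_I - 1 > max_gap:
                break  # order is ascending in index_I
            if _chainable(a, b, orientation, max_gap) and 1 + f[bi] > f[ai]:
                f[ai] = 1 + f[bi]
    total = max(f)
    cur = min(i for i in range(n) if f[i] == total)
    chain = [cur]
    need = total - 1
    while need:
        a = pairs[order[cur]]
        for bi in range(cur + 1, n):
            b = pairs[order[bi]]
            if b.index_I - a.index_I - 1 > max_gap:
                break
            if f[bi] == need and _chainable(a, b, orientation, max_gap):
                cur = bi
                break
        chain.append(cur)
        need -= 1
    return [order[k] for k in chain]


def _split_chain(chain: list, max_pairs: Optional[int]) -> list[list]:
    if max_pairs is None or len(chain) <= max_pairs:
        return [chain]
    k = -(-len(chain) // max_pairs)  # ceil
    size = -(-len(chain) // k)
    return [chain[i : i + size] for i in range(0, len(chain), size)]


def _block_from_pairs(members: list[HomologPair], orientation: int,
                      chrom_I: str, chrom_D: str) -> SyntenyBlock:
    s_i = min(p.span_I[0] for p in members)
    e_i = max(p.span_I[1] for p in members)
    s_d = min(p.span_D[0] for p in members)
    e_d = max(p.span_D[1] for p in members)
    return SyntenyBlock(chrom_I, chrom_D, (s_i, e_i), (s_d, e_d),
                        orientation, len(members), members)


def chain_synteny_blocks(
    pairs: Sequence[HomologPair],
    max_gap: int = 5,
    min_pairs: int = 4,
    chrom_I: str = "chrI",
    chrom_D: str = "chrD",
    max_pairs_per_block: Optional[int] = None,
) -> list[SyntenyBlock]:
    """Greedy extraction of maximal collinear chains into blocks.

    ``max_pairs_per_block`` optionally splits long chains into consecutive
    sub-blocks of balanced size, restoring the per-block resolution that
    annotation noise gives real chaining runs; oracle comparisons use the
    unsplit default.
    """
    min_pairs = max(min_pairs, 2)
    remaining = list(pairs)
    blocks: list[SyntenyBlock] = []
    while True:
        candidates = []
        for orientation in (1, -1):
            chain = _best_chain(remaining, orientation, max_gap)
            if len(chain) >= min_pairs:
                members = [remaining[k] for k in chain]
                candidates.append((len(chain), orientation, members))
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2][0].index_I))
        _n, orientation, members = candidates[0]
        for sub in _split_chain(members, max_pairs_per_block):
            if len(sub) >= 2:
                blocks.append(_block_from_pairs(sub, orientation, chrom_I, chrom_D))
        taken = {id(p) for p in members}
        remaining = [p for p in remaining if id(p) not in taken]
    blocks.sort(key=lambda b: b.span_I[0])
    return blocks


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    rows = [
        dict(
            chrom_I=b.chrom_I, start_I=b.span_I[0], end_I=b.span_I[1],
            chrom_D=b.chrom_D, start_D=b.span_D[0], end_D=b.span_D[1],
            orientation=b.orientation, n_pairs=b.n_pairs, size_ratio=b.size_ratio,
        )
        for b in blocks
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom_I", "start_I", "end_I", "chrom_D", "start_D", "end_D",
                 "orientation", "n_pairs", "size_ratio"],
    )


# ---------------------------------------------------------------------------
# Inversions and ratios
# ---------------------------------------------------------------------------


def detect_inversions(
    blocks: Sequence[SyntenyBlock], skip_tolerance: int = 0
) -> list[dict]:
    """Maximal runs of reverse-orientation blocks along genome I.

    Up to ``skip_tolerance`` interleaved forward blocks are absorbed into a
    run. Each region reports merged spans in both genomes and its member
    block count.
    """
    ordered = sorted(blocks, key=lambda b: b.span_I[0])
    regions = []
    run: list[SyntenyBlock] = []
    skips = 0
    for b in ordered + [None]:
        if b is not None and b.orientation == -1:
            run.append(b)
            skips = 0
            continue
        if b is not None and run and skips < skip_tolerance:
            skips += 1
            run.append(b)
            continue
        while run and run[-1].orientation == 1:
            run.pop()
        if run:
            regions.append(
                dict(
                    chrom_I=run[0].chrom_I,
                    chrom_D=run[0].chrom_D,
                    span_I=(min(x.span_I[0] for x in run), max(x.span_I[1] for x in run)),
                    span_D=(min(x.span_D[0] for x in run), max(x.span_D[1] for x in run)),
                    n_blocks=sum(1 for x in run if x.orientation == -1),
                )
            )
        run, skips = [], 0
    return regions


def size_ratio(len_I: float, len_D: float) -> float:
    """len_I / len_D; raises on a zero denominator. Rounding is left to
    presentation (reports print two decimals)."""
    if len_D == 0:
        raise DataError("size ratio undefined for zero-length denominator")
    return len_I / len_D


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def label_inverted_blocks(
    blocks: Sequence[SyntenyBlock], inverted_regions: Sequence[dict]
) -> list[bool]:
    """A block belongs to an inverted region if more than half of its I-span
    overlaps the region's I-span (same chromosome pair)."""
    labels = []
    for b in blocks:
        span_len = b.span_I[1] - b.span_I[0]
        inv = any(
            r["chrom_I"] == b.chrom_I
            and r["chrom_D"] == b.chrom_D
            and _overlap(b.span_I, r["span_I"]) * 2 > span_len
            for r in inverted_regions
        )
        labels.append(inv)
    return labels


@dataclass
class RegionRatioSummary:
    """Aggregate I/D size ratios (sum of spans) per region category."""

    inverted_ratio: Optional[float]
    non_inverted_ratio: Optional[float]
    excluded_chromosomes: list[str]
    per_block: pd.DataFrame  # ordered along genome D, with `inverted` labels


def region_ratio_summary(
    blocks: Sequence[SyntenyBlock],
    inverted_regions: Sequence[dict],
    excluded_chromosomes: Sequence[str] = (),
) -> RegionRatioSummary:
    """Overall size ratios for inverted vs non-inverted blocks.

    Ratios are length-weighted (sum of span_I over sum of span_D), matching
    how whole-region ratios are computed from member blocks; chromosomes in
    ``excluded_chromosomes`` (either genome's name) are dropped first. A
    category without blocks is reported as None, not zero.
    """
    excluded = set(excluded_chromosomes)
    kept = [
        (b, inv)
        for b, inv in zip(blocks, label_inverted_blocks(blocks, inverted_regions))
        if b.chrom_I not in excluded and b.chrom_D not in excluded
    ]

    def agg(selection):
        si = sum(b.span_I[1] - b.span_I[0] for b in selection)
        sd = sum(b.span_D[1] - b.span_D[0] for b in selection)
        return size_ratio(si, sd) if sd > 0 else None

    inv_blocks = [b for b, inv in kept if inv]
    non_blocks = [b for b, inv in kept if not inv]
    per_block = blocks_to_frame([b for b, _ in kept])
    per_block["inverted"] = [inv for _, inv in kept]
    per_block = per_block.sort_values(["chrom_D", "start_D"], kind="stable").reset_index(
        drop=True
    )
    return RegionRatioSummary(
        inverted_ratio=agg(inv_blocks) if inv_blocks else None,
        non_inverted_ratio=agg(non_blocks) if non_blocks else None,
        excluded_chromosomes=sorted(excluded),
        per_block=per_block,
    )
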