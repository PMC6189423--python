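"""Pairing, chaining (with exhaustive oracle), inversions, and ratios."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gsred import io
from gsred.errors import DataError
from gsred.synteny import (
    HomologPair,
    SyntenyBlock,
    chain_synteny_blocks,
    detect_inversions,
    find_homolog_pairs,
    label_inverted_blocks,
    region_ratio_summary,
    size_ratio,
)
from gsred.synthetic_data import map_ancestral_span


def mk_pairs(coords):
    """Build HomologPairs from (i_index, d_index) tuples; 1 kb genes."""
    return [
        HomologPair(
            f"gi{i:03d}", i, (i * 1000, i * 1000 + 900),
            f"gd{d:03d}", d, (d * 1000, d * 1000 + 900), 1.0,
        )
        for i, d in coords
    ]


def genes_frame(families, chrom="c"):
    return pd.DataFrame(
        dict(
            chrom=chrom,
            start=[i * 1000 for i in range(len(families))],
            end=[i * 1000 + 900 for i in range(len(families))],
            strand="+",
            kind="gene",
            feature_id=[f"{chrom}.g{i:03d}" for i in range(len(families))],
            family_id=families,
            te_class=None,
            template_id=None,
            is_solo=False,
            parent_id=None,
        )
    )


class TestPairing:
    def test_single_copy_families_pair_one_to_one(self):
        gi = genes_frame(["a", "b", "c"], "ci")
        gd = genes_frame(["a", "b", "c"], "cd")
        pairs = find_homolog_pairs(gi, gd)
        assert [(p.gene_I, p.gene_D) for p in pairs] == [
            ("ci.g000", "cd.g000"), ("ci.g001", "cd.g001"), ("ci.g002", "cd.g002")
        ]

    def test_equal_score_tie_breaks_to_smaller_target_id(self):
        gi = genes_frame(["dup"], "ci")
        gd = genes_frame(["dup", "dup"], "cd")
        pairs = find_homolog_pairs(gi, gd)
        assert len(pairs) == 1
        assert pairs[0].gene_D == "cd.g000"

    def test_empty_gene_set_gives_empty_list(self):
        gi = genes_frame([], "ci")
        gd = genes_frame(["a"], "cd")
        assert find_homolog_pairs(gi, gd) == []

    def test_fixture_pairing_matches_ortholog_truth(self, tiny_pair, tiny_bundle):
        truth = io.read_tsv(tiny_bundle.ortholog_truth)
        ann_I = io.read_annotation(tiny_bundle.gff_I)
        ann_D = io.read_annotation(tiny_bundle.gff_D)
        pairs = find_homolog_pairs(
            ann_I[ann_I.kind == "gene"], ann_D[ann_D.kind == "gene"]
        )
        got = {(p.gene_I, p.gene_D) for p in pairs}
        expected = set(zip(truth.gene_I, truth.gene_D))
        # tandem duplicates are ambiguous to a family-label scorer; for
        # single-copy families the pairing must equal the ancestral truth
        gi = ann_I[ann_I.kind == "gene"]
        multi = set(gi.family_id[gi.family_id.duplicated(keep=False)])
        single_ids = set(gi.feature_id[~gi.family_id.isin(multi)])
        assert {p for p in expected if p[0] in single_ids} <= got


# ---------------------------------------------------------------------------
# Chaining + oracle
# ---------------------------------------------------------------------------


def oracle_blocks(pairs, max_gap, min_pairs):
    """Exhaustive-enumeration oracle: all chains via DFS, canonical pick,
    greedy extraction loop mirroring the documented tie-breaks."""

    def compatible(a, b, orientation):
        if b.index_I <= a.index_I or b.index_I - a.index_I - 1 > max_gap:
            return False
        if orientation > 0:
            return 0 <= b.index_D - a.index_D - 1 <= max_gap
        return 0 <= a.index_D - b.index_D - 1 <= max_gap

    def best_chain(remaining, orientation):
        order = sorted(
            range(len(remaining)),
            key=lambda k: (remaining[k].index_I, remaining[k].index_D),
        )
        best: list[list[int]] = [[]]

        def dfs(chain):
            extended = False
            last = order[chain[-1]]
            for nxt in range(chain[-1] + 1, len(order)):
                if compatible(remaining[last], remaining[order[nxt]], orientation):
                    dfs(chain + [nxt])
                    extended = True
            if not extended:
                if len(chain) > len(best[0]) or (
                    len(chain) == len(best[0]) and chain < best[0]
                ):
                    best[0] = chain
        for start in range(len(order)):
            dfs([start])
        return [order[k] for k in best[0]]

    remaining = list(pairs)
    blocks = []
    while True:
        cands = []
        for orientation in (1, -1):
            chain = best_chain(remaining, orientation)
            if len(chain) >= max(min_pairs, 2):
                cands.append((len(chain), orientation, [remaining[k] for k in chain]))
        if not cands:
            break
        cands.sort(key=lambda c: (-c[0], -c[1], c[2][0].index_I))
        _n, orientation, members = cands[0]
        blocks.append((orientation, [(p.index_I, p.index_D) for p in members]))
        taken = {id(p) for p in members}
        remaining = [p for p in remaining if id(p) not in taken]
    # positional order, matching the chained output convention
    return sorted(blocks, key=lambda b: b[1][0][0])


def random_instance(rng):
    n = int(rng.integers(5, 41))
    side = max(12, n)
    cells = rng.choice(side * side, size=n, replace=False)
    return mk_pairs([(int(c // side), int(c % side)) for c in cells])


class TestChaining:
    def test_forward_run_single_block(self):
        blocks = chain_synteny_blocks(mk_pairs([(i, i) for i in range(6)]))
        assert len(blocks) == 1
        assert blocks[0].orientation == 1
        assert blocks[0].n_pairs == 6

    def test_reverse_run_single_block(self):
        blocks = chain_synteny_blocks(
            mk_pairs([(1, 6), (2, 5), (3, 4)]), min_pairs=3
        )
        assert len(blocks) == 1
        assert blocks[0].orientation == -1

    def test_blocks_do_not_overlap_within_a_genome(self, tiny_pair):
        ann_I = io.features_to_frame(tiny_pair.genome_I)
        ann_D = io.features_to_frame(tiny_pair.genome_D)
        pairs = find_homolog_pairs(
            ann_I[ann_I.kind == "gene"], ann_D[ann_D.kind == "gene"]
        )
        blocks = chain_synteny_blocks(pairs, max_pairs_per_block=8)
        spans = sorted(b.span_I for b in blocks)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_matches_exhaustive_oracle_on_small_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(60):
            pairs = random_instance(rng)
            max_gap = int(rng.integers(1, 6))
            min_pairs = int(rng.integers(2, 5))
            got = chain_synteny_blocks(pairs, max_gap=max_gap, min_pairs=min_pairs)
            got_repr = [
                (b.orientation, [(p.index_I, p.index_D) for p in b.pairs]) for b in got
            ]
            assert got_repr == oracle_blocks(pairs, max_gap, min_pairs), (
                trial, max_gap, min_pairs,
            )


class TestInversionsAndRatios:
    def _block(self, s_i, e_i, s_d, e_d, orientation, chrom=("ci", "cd")):
        return SyntenyBlock(chrom[0], chrom[1], (s_i, e_i), (s_d, e_d), orientation, 4)

    def test_all_forward_blocks_no_inversions(self):
        blocks = [self._block(i * 10, i * 10 + 8, i * 10, i * 10 + 8, 1) for i in range(4)]
        assert detect_inversions(blocks) == []

    def test_single_reverse_block_between_forward_neighbours(self):
        blocks = [
            self._block(0, 8, 0, 8, 1),
            self._block(10, 18, 10, 18, -1),
            self._block(20, 28, 20, 28, 1),
        ]
        regions = detect_inversions(blocks)
        assert len(regions) == 1
        assert regions[0]["span_I"] == (10, 18)
        assert regions[0]["span_D"] == (10, 18)

    def test_fixture_inversion_recovered_with_high_jaccard(self, tiny_pair):
        ann_I = io.features_to_frame(tiny_pair.genome_I)
        ann_D = io.features_to_frame(tiny_pair.genome_D)
        pairs = find_homolog_pairs(
            ann_I[ann_I.kind == "gene"], ann_D[ann_D.kind == "gene"]
        )
        blocks = chain_synteny_blocks(
            pairs, chrom_I="chr01_I", chrom_D="chr01_D", max_pairs_per_block=8
        )
        regions = detect_inversions(blocks)
        assert len(regions) == 1
        planted = tiny_pair.genome_D[0].log[0].span
        truth = map_ancestral_span(tiny_pair, "D", 0, planted)
        det = regions[0]["span_D"]
        inter = max(0, min(det[1], truth[1]) - max(det[0], truth[0]))
        union = max(det[1], truth[1]) - min(det[0], truth[0])
        assert inter / union >= 0.9

    def test_no_rearrangement_fixture_finds_no_inversions(self):
        from gsred.synthetic_data import fixture_pair

        pair = fixture_pair("no-rearrangement")
        ann_I = io.features_to_frame(pair.genome_I)
        ann_D = io.features_to_frame(pair.genome_D)
        pairs = find_homolog_pairs(
            ann_I[ann_I.kind == "gene"], ann_D[ann_D.kind == "gene"]
        )
        blocks = chain_synteny_blocks(
            pairs, chrom_I="chr01_I", chrom_D="chr01_D", max_pairs_per_block=8
        )
        assert detect_inversions(blocks) == []

    def test_size_ratio_definition_and_errors(self):
        assert size_ratio(150, 100) == pytest.approx(1.5)
        assert size_ratio(100, 100) == pytest.approx(1.0)
        with pytest.raises(DataError):
            size_ratio(100, 0)

    def test_summary_of_unit_ratio_blocks_is_one(self):
        blocks = [self._block(i * 10, i * 10 + 8, i * 10, i * 10 + 8, 1) for i in range(4)]
        blocks += [self._block(50, 58, 50, 58, -1)]
        regions = detect_inversions(blocks)
        summary = region_ratio_summary(blocks, regions)
        assert summary.inverted_ratio == pytest.approx(1.0)
        assert summary.non_inverted_ratio == pytest.approx(1.0)

    def test_empty_category_reported_as_undefined(self):
        blocks = [self._block(0, 8, 0, 8, 1)]
        summary = region_ratio_summary(blocks, [])
        assert summary.inverted_ratio is None
        assert summary.non_inverted_ratio == pytest.approx(1.0)

    def test_excluded_chromosomes_dropped(self):
        blocks = [
            self._block(0, 10, 0, 5, 1),
            self._block(0, 10, 0, 10, 1, chrom=("ci7", "cd7")),
        ]
        summary = region_ratio_summary(blocks, [], excluded_chromosomes=["ci7"])
        assert summary.non_inverted_ratio == pytest.approx(2.0)

    def test_inverted_label_uses_majority_overlap(self):
        blocks = [self._block(0, 10, 0, 10, -1), self._block(9, 30, 9, 30, 1)]
        regions = [dict(chrom_I="ci", chrom_D="cd", span_I=(0, 10), span_D=(0, 10))]
        assert label_inverted_blocks(blocks, regions) == [True, False]
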