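"""Serialization, sequence synthesis, marker maps, and fixture registry."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gsred import io
from gsred.errors import ConfigError
from gsred.sim_core import RecombinationMap, SimConfig, simulate_divergent_pair, terminal_inversion_plan
from gsred.synthetic_data import (
    SequenceSynthesizer,
    alignment_blocks,
    fixture_pair,
    map_ancestral_span,
    sample_marker_map,
    write_genome_pair,
)
from gsred import forensics


class TestSequencesAndRoundTrip:
    def test_fasta_lengths_match_states(self, tiny_pair, tiny_bundle):
        for tag, fasta in (("I", tiny_bundle.fasta_I), ("D", tiny_bundle.fasta_D)):
            seqs = io.read_fasta(fasta)
            for chrom in tiny_pair.lineage(tag):
                assert len(seqs[chrom.name]) == chrom.length

    def test_gff_round_trip_recovers_feature_tiling(self, tiny_pair, tiny_bundle):
        cols = ["chrom", "start", "end", "strand", "kind", "family_id"]
        for tag, gff in (("I", tiny_bundle.gff_I), ("D", tiny_bundle.gff_D)):
            genome = tiny_pair.lineage(tag)
            parsed = io.read_annotation(gff, seq_lengths={c.name: c.length for c in genome})
            mem = io.features_to_frame(genome)
            a = parsed[parsed.kind != "ltr_terminus"][cols].reset_index(drop=True)
            b = mem[mem.kind != "ltr_terminus"][cols].reset_index(drop=True)
            pd.testing.assert_frame_equal(a.fillna(""), b.fillna(""))

    def test_orthologs_share_sequence(self, tiny_pair, tiny_bundle):
        """Gene copies descending from one ancestral copy are written with
        identical sequence in both genomes (homology is real)."""
        truth = io.read_tsv(tiny_bundle.ortholog_truth)
        seqs_I = io.read_fasta(tiny_bundle.fasta_I)
        seqs_D = io.read_fasta(tiny_bundle.fasta_D)
        ann_I = io.read_annotation(tiny_bundle.gff_I).set_index("feature_id")
        ann_D = io.read_annotation(tiny_bundle.gff_D).set_index("feature_id")
        row = truth.iloc[0]
        gi, gd = ann_I.loc[row.gene_I], ann_D.loc[row.gene_D]
        si = seqs_I[gi.chrom][gi.start : gi.end]
        sd = seqs_D[gd.chrom][gd.start : gd.end]
        from gsred.synthetic_data import revcomp

        assert si == sd or si == revcomp(sd)


class TestAlignmentBlocks:
    def test_zero_generation_pair_gives_forward_plus_one_reverse_run(self):
        cfg = SimConfig(chromosome_length=200_000, n_generations=0, rng_seed=3)
        plan = terminal_inversion_plan(cfg)
        pair = simulate_divergent_pair(cfg, plan)
        ab = alignment_blocks(pair)
        rev = ab[ab.orientation == -1]
        assert len(rev) == 1
        planted = pair.genome_D[0].log[0].span
        assert int(rev.start_D.iloc[0]) == planted[0]
        assert int(rev.end_D.iloc[0]) == planted[1]
        # every ancestral base appears exactly once in each genome
        assert (ab.end_I - ab.start_I).sum() == pair.ancestors[0].length
        assert (ab.end_D - ab.start_D).sum() == pair.ancestors[0].length

    def test_aligned_plus_unaligned_equals_length(self, tiny_pair):
        ab = alignment_blocks(tiny_pair)
        lengths = {
            tag: {c.name: c.length for c in tiny_pair.lineage(tag)} for tag in "ID"
        }
        segs = forensics.extract_unaligned_segments(ab, lengths)
        for tag in "ID":
            aligned = (ab[f"end_{tag}"] - ab[f"start_{tag}"]).sum()
            unaligned = segs[tag].length.sum()
            assert aligned + unaligned == sum(lengths[tag].values())

    def test_unaligned_segments_recover_deletion_truth(self):
        """With insertions off, each deletion in D maps to an unaligned
        segment in I covering the removed ancestral interval (Jaccard >= 0.95)."""
        cfg = SimConfig(
            chromosome_length=300_000, n_generations=150, rng_seed=21,
            lambda_insert=0.0, lambda_unequal=0.0,
        )
        pair = simulate_divergent_pair(cfg, terminal_inversion_plan(cfg))
        ab = alignment_blocks(pair)
        lengths = {tag: {c.name: c.length for c in pair.lineage(tag)} for tag in "ID"}
        segs_I = forensics.extract_unaligned_segments(ab, lengths)["I"]
        intervals = [(s, e) for s, e in zip(segs_I.start, segs_I.end)]
        anc = pair.ancestors[0]
        offsets = {f.src[0]: f.start for f in anc.features if f.src is not None}
        # the deletion truth is the union of removed ancestral intervals:
        # adjacent/overlapping deletions in D merge into one unaligned segment
        removed = sorted(
            (offsets[sid] + lo, offsets[sid] + hi)
            for ev in pair.genome_D[0].log
            if ev.kind == "illegitimate_deletion"
            for sid, lo, hi in ev.detail["removed_src"]
            if sid in offsets
        )
        runs: list[list[int]] = []
        for s, e in removed:
            if runs and s <= runs[-1][1]:
                runs[-1][1] = max(runs[-1][1], e)
            else:
                runs.append([s, e])
        n_checked = 0
        for anc_lo, anc_hi in runs:
            span = map_ancestral_span(pair, "I", 0, (anc_lo, anc_hi))
            if span is None:
                continue
            best = 0.0
            for s, e in intervals:
                inter = max(0, min(e, span[1]) - max(s, span[0]))
                union = max(e, span[1]) - min(s, span[0])
                best = max(best, inter / union)
            assert best >= 0.95
            n_checked += 1
        assert n_checked > 10


class TestMarkerMap:
    def test_constant_rate_gives_equal_spacing(self):
        m = RecombinationMap(1_000_000, 500_000, c_min=0.5, c_max=0.5,
                             total_map_length_cM=100.0)
        table = sample_marker_map(m, 11, np.random.default_rng(0))
        steps = np.diff(table.cM.to_numpy())
        assert np.allclose(steps, steps[0], atol=0.2)

    def test_total_map_length_recovered(self):
        m = RecombinationMap(1_000_000, 500_000, total_map_length_cM=150.0)
        table = sample_marker_map(m, 50, np.random.default_rng(0))
        assert table.cM.iloc[-1] == pytest.approx(150.0, rel=0.005)

    def test_monotone_and_distal_enrichment(self):
        m = RecombinationMap(1_000_000, 500_000)
        table = sample_marker_map(m, 101, np.random.default_rng(0))
        cm = table.cM.to_numpy()
        assert np.all(np.diff(cm) >= 0)
        bp = table.position_bp.to_numpy()
        rate = np.diff(cm) / np.diff(bp)
        distal = rate[bp[1:] <= 250_000]
        pericentromeric = rate[(bp[1:] > 375_000) & (bp[1:] <= 500_000)]
        assert distal.mean() > pericentromeric.mean()

    def test_too_few_markers_rejected(self):
        m = RecombinationMap(10_000, 5_000)
        with pytest.raises(ConfigError):
            sample_marker_map(m, 1, np.random.default_rng(0))


class TestFixtures:
    def test_unknown_fixture_name_rejected(self):
        with pytest.raises(ConfigError):
            fixture_pair("not-a-fixture")

    def test_planted_solo_fixture_counts(self):
        pair = fixture_pair("solo-ltr-planted")
        chrom_d = pair.genome_D[0]
        assert len(chrom_d.intact_ltr_features()) == 5
        assert sum(1 for f in chrom_d.features if f.is_solo_ltr) == 3
        assert len(pair.genome_I[0].intact_ltr_features()) == 8
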