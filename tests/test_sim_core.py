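"""Simulator unit and property tests: builders, operators, dynamics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gsred.errors import BoundsError, ConfigError, ProtectedBreakpointError
from gsred.sim_core import (
    ChromosomeState,
    Feature,
    RecombinationMap,
    SimConfig,
    apply_inversion,
    apply_relocation,
    build_ancestral_chromosome,
    clone_chromosome,
    convert_to_solo,
    delete_span,
    recombination_rate_at,
    replay_chromosome,
    simulate_divergent_pair,
    snap_to_boundary,
    step_generation,
    terminal_inversion_plan,
)
from gsred.synthetic_data import surviving_bp


def small_config(**kw):
    kw.setdefault("chromosome_length", 200_000)
    kw.setdefault("n_generations", 50)
    return SimConfig(**kw)


# ---------------------------------------------------------------------------
# Recombination map
# ---------------------------------------------------------------------------


class TestRecombinationMap:
    def test_minimum_at_centromere_and_monotone_arms(self):
        m = RecombinationMap(1_000_000, 450_000)
        grid = np.arange(0, 1_000_000, 1_000)
        c = m.rate_at(grid)
        cen_idx = np.argmin(np.abs(grid - 450_000))
        assert c[cen_idx] == pytest.approx(c.min(), abs=1e-9)
        # non-increasing from each telomere toward the centromere
        left = c[: cen_idx + 1]
        right = c[cen_idx:]
        assert np.all(np.diff(left) <= 1e-12)
        assert np.all(np.diff(right) >= -1e-12)
        assert recombination_rate_at(m, 0) >= recombination_rate_at(m, 450_000)

    def test_integrated_rate_recovers_total_map_length(self):
        # quadrature oracle: integrate the local cM/bp slope on a 1 kb grid
        m = RecombinationMap(2_000_000, 1_000_000, total_map_length_cM=137.0)
        grid = np.arange(0, 2_000_000, 1_000, dtype=float)
        cm = m.genetic_position(grid)
        slope = np.gradient(cm, grid)
        total = np.trapezoid(slope, grid)
        assert total == pytest.approx(137.0, rel=0.01)

    def test_position_bounds_checked(self):
        m = RecombinationMap(10_000, 5_000)
        with pytest.raises(BoundsError):
            recombination_rate_at(m, 10_000)
        with pytest.raises(BoundsError):
            recombination_rate_at(m, -1)


# ---------------------------------------------------------------------------
# Ancestral chromosome
# ---------------------------------------------------------------------------


class TestAncestor:
    def test_zero_te_weights_yield_gene_spacer_chromosome(self):
        cfg = small_config(te_weight_min=0.0, te_weight_max=0.0)
        chrom = build_ancestral_chromosome(cfg, 0, np.random.default_rng(0))
        assert all(f.kind != "te" for f in chrom.features)
        assert any(f.kind == "gene" for f in chrom.features)

    def test_u_shape_and_te_anticorrelation(self):
        cfg = SimConfig(chromosome_length=1_200_000, rng_seed=1)
        chrom = build_ancestral_chromosome(cfg, 0, np.random.default_rng(1))
        # brute-force per-partition counting over the emitted feature list
        n_part = 500
        base = chrom.length // n_part
        gene_counts = np.zeros(n_part)
        te_counts = np.zeros(n_part)
        for f in chrom.features:
            idx = min(((f.start + f.end) // 2) // base, n_part - 1)
            if f.kind == "gene":
                gene_counts[idx] += 1
            elif f.kind == "te":
                te_counts[idx] += 1
        outer = np.r_[gene_counts[: n_part // 10], gene_counts[-n_part // 10 :]]
        middle = gene_counts[2 * n_part // 5 : 3 * n_part // 5]
        assert outer.mean() > middle.mean()
        rho = sps.spearmanr(gene_counts, te_counts).statistic
        assert rho < 0

    def test_determinism_same_seed_same_features(self):
        cfg = small_config(rng_seed=5)
        a = build_ancestral_chromosome(cfg, 0, np.random.default_rng(42))
        b = build_ancestral_chromosome(cfg, 0, np.random.default_rng(42))
        assert a.features == b.features

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            build_ancestral_chromosome(
                small_config(chromosome_length=1_000), 0, np.random.default_rng(0)
            )


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------


def toy_chromosome(kinds=("gene", "te", "spacer", "gene", "te")):
    feats = []
    pos = 0
    for i, kind in enumerate(kinds):
        ln = 100 * (i + 1)
        feats.append(
            Feature(kind, pos, pos + ln, "+", family_id=f"f{i}",
                    te_class="DNA" if kind == "te" else None,
                    src=(i, 0, ln))
        )
        pos += ln
    return ChromosomeState("toy", feats, pos, RecombinationMap(pos, pos // 2))


class TestInversion:
    def test_double_inversion_is_identity(self):
        chrom = toy_chromosome()
        before = [f.copy() for f in chrom.features]
        apply_inversion(chrom, 0, chrom.length)
        apply_inversion(chrom, 0, chrom.length)
        assert chrom.features == before

    def test_middle_three_reversed_with_flipped_strands(self):
        chrom = toy_chromosome()
        s = chrom.features[1].start
        e = chrom.features[3].end
        apply_inversion(chrom, s, e)
        fams = [f.family_id for f in chrom.features]
        assert fams == ["f0", "f3", "f2", "f1", "f4"]
        assert [f.strand for f in chrom.features] == ["+", "-", "-", "-", "+"]
        chrom.validate()

    def test_gene_breakpoint_protected(self):
        chrom = toy_chromosome()
        inside_gene = chrom.features[0].start + 50
        with pytest.raises(ProtectedBreakpointError):
            apply_inversion(chrom, inside_gene, chrom.length)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        kinds=st.lists(st.sampled_from(["gene", "te", "spacer"]), min_size=2, max_size=12),
        data=st.data(),
    )
    def test_involution_and_conservation_property(self, kinds, data):
        chrom = toy_chromosome(tuple(kinds))
        boundaries = [0] + [f.end for f in chrom.features]
        i = data.draw(st.integers(0, len(boundaries) - 2))
        j = data.draw(st.integers(i + 1, len(boundaries) - 1))
        s, e = boundaries[i], boundaries[j]
        before = [f.copy() for f in chrom.features]
        multiset = sorted((f.kind, f.family_id, f.length) for f in before)
        apply_inversion(chrom, s, e)
        chrom.validate()
        assert sorted((f.kind, f.family_id, f.length) for f in chrom.features) == multiset
        apply_inversion(chrom, s, e)
        assert chrom.features == before


class TestRelocation:
    def test_relocation_onto_own_position_is_identity(self):
        chrom = toy_chromosome()
        before = [f.copy() for f in chrom.features]
        s, e = chrom.features[1].start, chrom.features[2].end
        apply_relocation(chrom, (s, e), chrom, s, record=False)
        assert chrom.features == before

    def test_length_conservation_between_chromosomes(self):
        a, b = toy_chromosome(), toy_chromosome(("spacer", "te", "spacer"))
        la, lb = a.length, b.length
        s, e = a.features[1].start, a.features[2].end
        moved = e - s
        apply_relocation(a, (s, e), b, b.length)
        a.validate()
        b.validate()
        assert a.length == la - moved
        assert b.length == lb + moved

    def test_relocated_pericentromeric_span_loses_more(self):
        """Exposing a pericentromeric span to a telomeric environment
        accelerates its loss relative to an identical unmoved control."""
        cfg = small_config(chromosome_length=400_000, lambda_unequal=0.0,
                           lambda_insert=0.0, rng_seed=11)
        ancestor = build_ancestral_chromosome(cfg, 0, np.random.default_rng(11))
        span = (snap_to_boundary(ancestor, 180_000), snap_to_boundary(ancestor, 200_000))
        moved = clone_chromosome(ancestor, "moved")
        apply_relocation(moved, span, moved, moved.length)
        control = clone_chromosome(ancestor, "control")
        rng_m, rng_c = np.random.default_rng(7), np.random.default_rng(7)
        for _ in range(2_000):
            step_generation(moved, cfg, rng_m)
            step_generation(control, cfg, rng_c)
        lost_moved = (span[1] - span[0]) - surviving_bp(ancestor, moved, span)
        lost_control = (span[1] - span[0]) - surviving_bp(ancestor, control, span)
        assert lost_moved > lost_control


# ---------------------------------------------------------------------------
# Per-generation dynamics
# ---------------------------------------------------------------------------


class TestStepGeneration:
    def test_null_dynamics_only_advances_generation(self):
        cfg = small_config(lambda_illegit=0, lambda_unequal=0, lambda_insert=0)
        chrom = build_ancestral_chromosome(cfg, 0, np.random.default_rng(3))
        before = [f.copy() for f in chrom.features]
        step_generation(chrom, cfg, np.random.default_rng(0))
        assert chrom.generation == 1
        assert chrom.features == before

    def test_first_unequal_event_leaves_one_solo(self):
        cfg = small_config(lambda_illegit=0, lambda_insert=0, lambda_unequal=5e-3)
        chrom = build_ancestral_chromosome(cfg, 0, np.random.default_rng(8))
        k = len(chrom.intact_ltr_features())
        assert k > 0
        L0 = chrom.length
        rng = np.random.default_rng(8)
        while not chrom.log:
            step_generation(chrom, cfg, rng)
        ev = chrom.log[0]
        assert ev.kind == "unequal_intrastrand_deletion"
        assert len(chrom.intact_ltr_features()) == k - 1
        solos = [f for f in chrom.features if f.is_solo_ltr]
        assert len(solos) == 1
        element_len = ev.span[1] - ev.span[0]
        assert chrom.length == L0 - (element_len - solos[0].length)

    def test_loss_scales_linearly_with_recombination_rate(self):
        """Doubling c doubles expected bp lost (t-test keeps ratio = 2)."""
        losses = {c: [] for c in (0.3, 0.6)}
        for seed in range(30):
            for c in losses:
                cfg = SimConfig(
                    chromosome_length=200_000, gene_weight_min=0.0,
                    gene_weight_max=0.0, c_min=c, c_max=c,
                    lambda_illegit=5e-7, lambda_unequal=0.0, lambda_insert=0.0,
                    n_generations=600, rng_seed=seed,
                )
                chrom = build_ancestral_chromosome(cfg, 0, np.random.default_rng(seed))
                rng = np.random.default_rng((seed, int(c * 10)))
                for _ in range(cfg.n_generations):
                    step_generation(chrom, cfg, rng)
                losses[c].append(200_000 - chrom.length)
        d = np.array(losses[0.6]) - 2.0 * np.array(losses[0.3])
        p = sps.ttest_1samp(d, 0.0).pvalue
        assert p > 0.01

    def test_gene_bp_conserved_under_protection(self):
        cfg = small_config(rng_seed=2, n_generations=300)
        pair = simulate_divergent_pair(cfg, terminal_inversion_plan(cfg))
        anc_gene_bp = sum(c.gene_bp() for c in pair.ancestors)
        for genome in (pair.genome_I, pair.genome_D):
            assert sum(c.gene_bp() for c in genome) == anc_gene_bp


# ---------------------------------------------------------------------------
# Divergent pair, ledger, replay
# ---------------------------------------------------------------------------


class TestDivergentPair:
    def test_zero_generations_differ_only_by_inversion(self):
        cfg = small_config(n_generations=0, rng_seed=9)
        plan = terminal_inversion_plan(cfg)
        pair = simulate_divergent_pair(cfg, plan)
        ci, cd = pair.genome_I[0], pair.genome_D[0]
        assert ci.length == cd.length
        assert ci.features != cd.features
        # undo the planned inversion: D becomes I
        ev = cd.log[0]
        assert ev.kind == "inversion"
        apply_inversion(cd, *ev.span, record=False)
        assert [
            (f.kind, f.start, f.end, f.strand) for f in cd.features
        ] == [(f.kind, f.start, f.end, f.strand) for f in ci.features]

    def test_truth_replay_and_ledger_identity(self):
        cfg = small_config(rng_seed=4, n_generations=400)
        pair = simulate_divergent_pair(cfg, terminal_inversion_plan(cfg))
        for genome in (pair.genome_I, pair.genome_D):
            for anc, chrom in zip(pair.ancestors, genome):
                chrom.validate()
                replayed = replay_chromosome(anc, chrom.log)
                assert replayed.features == chrom.features
                assert replayed.length == chrom.length
                assert chrom.length == anc.length + sum(
                    ev.length_change for ev in chrom.log
                )

    def test_same_seed_reproduces_simulation(self):
        cfg = small_config(rng_seed=13, n_generations=200)
        p1 = simulate_divergent_pair(cfg, terminal_inversion_plan(cfg))
        p2 = simulate_divergent_pair(
            small_config(rng_seed=13, n_generations=200),
            terminal_inversion_plan(cfg),
        )
        for g1, g2 in ((p1.genome_I, p2.genome_I), (p1.genome_D, p2.genome_D)):
            for c1, c2 in zip(g1, g2):
                assert c1.features == c2.features

    def test_monotone_loss_in_recombination_rate(self):
        """Expected loss from a fixed span is non-decreasing in c."""
        mean_loss = []
        for c in (0.1, 0.4, 0.9):
            tot = 0
            for seed in range(15):
                cfg = SimConfig(
                    chromosome_length=150_000, gene_weight_min=0.0, gene_weight_max=0.0,
                    c_min=c, c_max=c, lambda_illegit=2e-6, lambda_unequal=0.0,
                    lambda_insert=0.0, n_generations=300, rng_seed=seed,
                )
                chrom = build_ancestral_chromosome(cfg, 0, np.random.default_rng(seed))
                rng = np.random.default_rng((seed, int(c * 10)))
                for _ in range(cfg.n_generations):
                    step_generation(chrom, cfg, rng)
                tot += 150_000 - chrom.length
            mean_loss.append(tot / 15)
        assert mean_loss[0] < mean_loss[1] < mean_loss[2]


class TestDeleteSpan:
    def test_removed_source_slices_cover_span(self):
        chrom = toy_chromosome()
        ev = delete_span(chrom, 150, 450)
        chrom.validate()
        assert ev.length_change == -300
        assert sum(hi - lo for _sid, lo, hi in ev.detail["removed_src"]) == 300

    def test_solo_conversion_retains_five_prime_terminus(self):
        spec_len, term = 1_000, 150
        feats = [
            Feature("spacer", 0, 500, "+", src=(0, 0, 500)),
            Feature("te", 500, 500 + spec_len, "-", family_id="LTR_famX",
                    te_class="LTR", ltr_termini=(term, term), src=(1, 0, spec_len)),
            Feature("spacer", 1_500, 2_000, "+", src=(2, 0, 500)),
        ]
        chrom = ChromosomeState("t", feats, 2_000, RecombinationMap(2_000, 1_000))
        ev = convert_to_solo(chrom, feats[1])
        chrom.validate()
        solo = [f for f in chrom.features if f.is_solo_ltr][0]
        assert solo.length == term
        # '-' strand: 5' terminus is the right-hand one in genome coordinates
        assert ev.detail["solo_interval"] == (500 + spec_len - term, 500 + spec_len)
        assert chrom.length == 2_000 - (spec_len - term)
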