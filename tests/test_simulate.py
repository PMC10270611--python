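import math
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import chisquare

from lexiclade.cognacy import cognacy_diversity
from lexiclade.geo import great_circle_angle
from lexiclade.simulate import (
    SimConfig,
    angle_mean_square,
    simulate_covarion_matrix,
    simulate_geography,
    simulate_tree,
    simulate_wordlist,
)
from lexiclade.trees import rf_distance


class TestSimulateTree:
    def test_same_seed_identical(self):
        cfg = SimConfig(seed=5, n_taxa=9, root_age=2500)
        t1, t2 = simulate_tree(cfg), simulate_tree(cfg)
        assert t1.to_newick() == t2.to_newick()
        assert rf_distance(t1, t2) == 0

    def test_zero_log_sd_gives_constant_rates(self):
        cfg = SimConfig(seed=5, n_taxa=6, clock_log_sd=0.0, clock_mean=3e-4)
        t = simulate_tree(cfg)
        assert np.allclose(t.rates, 3e-4)

    def test_root_age_and_validity(self):
        cfg = SimConfig(seed=8, n_taxa=12, root_age=4100)
        t = simulate_tree(cfg)
        t.validate()
        assert np.isclose(t.heights[t.root], 4100)
        assert np.allclose(t.heights[: t.n_tips], 0.0)

    def test_yule_ranked_topologies_uniform(self):
        """Pure-birth labelled histories on 4 taxa are uniform (18 classes)."""
        def history(t):
            order = sorted((i for i in range(t.n_nodes) if not t.is_tip(i)),
                           key=lambda i: t.heights[i])
            sets = t.tipsets()
            return tuple("|".join(sorted(",".join(sorted(sets[c]))
                                         for c in t.children[i])) for i in order)

        counts = Counter()
        cfg = SimConfig(seed=0, n_taxa=4, death=0.0, birth=1e-3)
        for k in range(2000):
            t = simulate_tree(replace(cfg, seed=10_000 + k))
            counts[history(t)] += 1
        assert len(counts) == 18
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            SimConfig(birth=1e-4, death=2e-4)


class TestSimulateWordlist:
    def test_static_lexicon_fully_cognate(self):
        cfg = SimConfig(seed=5, n_taxa=6, n_concepts=8, gain_rate=0.0, loss_rate=0.0)
        tree = simulate_tree(cfg)
        wl, truth = simulate_wordlist(tree, cfg)
        assert cognacy_diversity(wl) == 0.0
        assert truth.n_chars == 8

    def test_two_taxon_pattern_frequencies_match_closed_form(self):
        """switch 0, alpha 1: pure-loss binary process with analytic pattern
        probabilities, conditioned on the concept surviving somewhere."""
        from lexiclade.trees import Tree

        n = 5000
        cfg = SimConfig(seed=3, n_taxa=2, n_concepts=n, root_age=1.0,
                        clock_mean=1.0, clock_log_sd=0.0, switch_rate=0.0,
                        alpha=1.0, loss_rate=0.6, gain_rate=0.0,
                        coverage_range=(1.0, 1.0))
        tree = Tree.from_newick("(A:1,B:1);")
        tree.rates[:] = 1.0
        wl, truth = simulate_wordlist(tree, cfg, np.random.default_rng(3))
        p = math.exp(-0.6)  # survival probability per tip
        probs = {"11": p * p, "10": p * (1 - p), "01": (1 - p) * p}
        z = sum(probs.values())  # all-absent concepts are resimulated
        obs = Counter()
        for j in range(truth.n_chars):
            col = truth.cells[:, j]
            obs["".join(str(int(v)) for v in col)] += 1
        keys = sorted(probs)
        stat, pval = chisquare([obs[k] for k in keys],
                               [n * probs[k] / z for k in keys])
        assert pval > 0.01

    def test_coverage_range_controls_attestation(self):
        cfg = SimConfig(seed=4, n_taxa=6, n_concepts=200, coverage_range=(0.5, 0.5))
        tree = simulate_tree(cfg)
        wl, _ = simulate_wordlist(tree, cfg)
        for d in wl.doculects:
            assert abs(d.coverage - 0.5) < 0.15  # binomial noise around 50%

    def test_same_seed_identical(self):
        cfg = SimConfig(seed=11, n_taxa=5, n_concepts=20)
        tree = simulate_tree(cfg)
        wl1, m1 = simulate_wordlist(tree, cfg)
        wl2, m2 = simulate_wordlist(tree, cfg)
        assert np.array_equal(m1.cells, m2.cells)
        assert [e.cognate_set_id for e in wl1.entries] == \
            [e.cognate_set_id for e in wl2.entries]

    def test_root_meaning_invariant(self):
        cfg = SimConfig(seed=12, n_taxa=8, n_concepts=30, gain_rate=0.8)
        tree = simulate_tree(cfg)
        wl, _ = simulate_wordlist(tree, cfg)
        wl.validate()  # raises if a set id appears under two concepts


class TestSimulateGeography:
    def test_huge_tau_pins_tips_to_root(self):
        cfg = SimConfig(seed=6, n_taxa=6, tau=1e12)
        tree = simulate_tree(cfg)
        locs = simulate_geography(tree, cfg)
        root = locs[tree.root]
        for i in range(tree.n_tips):
            assert math.degrees(great_circle_angle(root, locs[i])) < 0.01

    def test_mean_squared_displacement_matches_kernel(self):
        """Tip MSD equals the sum over branches of E[θ²|v] (within 20%)."""
        cfg = SimConfig(seed=7, n_taxa=2, tau=3000.0, root_age=1500.0)
        from lexiclade.trees import Tree

        tree = Tree.from_newick("(A:1500,B:1500);")
        tree.rates[:] = 1.0
        expect = angle_mean_square(1500.0 / 3000.0)
        sq = []
        for k in range(200):
            locs = simulate_geography(tree, replace(cfg, seed=100 + k))
            sq.append(great_circle_angle(locs[tree.root], locs[0]) ** 2)
        assert abs(np.mean(sq) - expect) / expect < 0.2

    def test_same_seed_identical(self):
        cfg = SimConfig(seed=9, n_taxa=5)
        tree = simulate_tree(cfg)
        l1 = simulate_geography(tree, cfg)
        l2 = simulate_geography(tree, cfg)
        assert all(l1[i] == l2[i] for i in l1)


class TestCovarionMatrix:
    def test_observable_conditioning(self):
        cfg = SimConfig(seed=2, n_taxa=6)
        tree = simulate_tree(cfg)
        from lexiclade.covarion import CovarionParams

        m = simulate_covarion_matrix(tree, CovarionParams(0.5, 0.5), 100,
                                     np.random.default_rng(0))
        assert ((m.cells == 1).sum(axis=0) >= 1).all()
        assert m.n_chars == 100
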