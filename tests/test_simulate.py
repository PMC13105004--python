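"""Synthetic-data generators: trees, Gillespie counts, tables, Brownian traits."""

import numpy as np
import pandas as pd
import pytest

import karyotempo as kt
from karyotempo.model import build_rate_matrix, transition_matrix
from karyotempo.simulate import evolve_branch, _branch_rng


class TestYuleTree:
    def test_two_tips_is_unit_cherry(self):
        tree = kt.simulate_yule_tree(2, seed=0)
        assert tree.n_tips == 2
        lengths = [n.edge.length for n in tree.tree.leaf_node_iter()]
        assert lengths == pytest.approx([1.0, 1.0])

    def test_deterministic_newick(self):
        a = kt.simulate_yule_tree(100, seed=1).as_newick()
        b = kt.simulate_yule_tree(100, seed=1).as_newick()
        assert a == b
        c = kt.simulate_yule_tree(100, seed=2).as_newick()
        assert a != c

    def test_ultrametric_by_construction(self):
        tree = kt.simulate_yule_tree(50, seed=3)
        report = kt.validate_ultrametric(tree, rel_tol=1e-9)
        assert report.ok
        assert tree.depth == pytest.approx(1.0, abs=1e-12)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            kt.simulate_yule_tree(1, seed=0)


class TestSimulateCounts:
    def test_zero_rates_keep_root_state(self):
        tree = kt.simulate_yule_tree(40, seed=4)
        space = kt.StateSpace(1, 20)
        counts, events = kt.simulate_counts(tree, space, kt.RateParams(), 9, seed=5)
        assert (counts["haploid_n"] == 9).all()
        assert events.empty

    def test_single_branch_pure_gain_is_poisson(self):
        # far from the boundary the gain-only chain is a Poisson counter
        space = kt.StateSpace(1, 1000)
        Q = build_rate_matrix(space, kt.RateParams(gain=2.0))
        rng = np.random.default_rng(12)
        jumps = []
        for _ in range(2000):
            end, ev = evolve_branch(space.index(100), 1.0, Q, rng)
            jumps.append(space.count(end) - 100)
        assert 1.85 <= np.mean(jumps) <= 2.15

    def test_dominant_polyploidy_first_event_doubles(self):
        space = kt.StateSpace(1, 64)
        Q = build_rate_matrix(space, kt.RateParams(poly=5.0))
        rng = np.random.default_rng(9)
        for _ in range(50):
            _, events = evolve_branch(space.index(4), 10.0, Q, rng)
            if events:
                assert space.count(events[0][2]) == 8
                break

    def test_reproducible_and_seed_sensitive(self):
        tree = kt.simulate_yule_tree(30, seed=6)
        space = kt.StateSpace(1, 30)
        params = kt.RateParams(gain=0.8, loss=0.8)
        c1, e1 = kt.simulate_counts(tree, space, params, 10, seed=7)
        c2, e2 = kt.simulate_counts(tree, space, params, 10, seed=7)
        c3, _ = kt.simulate_counts(tree, space, params, 10, seed=8)
        assert c1.equals(c2) and e1.equals(e2)
        assert not c1.equals(c3)

    def test_event_log_replays_to_tip_states(self):
        tree = kt.simulate_yule_tree(25, seed=10)
        space = kt.StateSpace(1, 40)
        params = kt.RateParams(gain=1.5, loss=1.0, poly=0.3, demi=0.2)
        counts, events = kt.simulate_counts(tree, space, params, 10, seed=11)
        # replay: final state per branch key follows by applying events in order
        from karyotempo.simulate import _branch_keys

        keys = _branch_keys(tree)
        states = {id(tree.tree.seed_node): 10}
        for node in tree.tree.preorder_node_iter():
            if node is tree.tree.seed_node:
                continue
            s = states[id(node.parent_node)]
            branch_events = events[events["branch"] == keys[id(node)]]
            for _, row in branch_events.sort_values("time").iterrows():
                assert row["from"] == s
                s = int(row["to"])
            states[id(node)] = s
            if node.is_leaf():
                expected = counts.set_index("species").loc[node.taxon.label, "haploid_n"]
                assert s == expected

    def test_marginal_matches_transition_matrix(self):
        # one branch of length t: empirical tip-state frequencies vs exp(Qt) row
        space = kt.StateSpace(1, 30)
        params = kt.RateParams(gain=0.8, loss=0.5, poly=0.2, demi=0.1)
        Q = build_rate_matrix(space, params)
        t = 0.7
        row = transition_matrix(Q, t)[space.index(10)]
        rng = np.random.default_rng(13)
        freq = np.zeros(space.size)
        n = 4000
        for _ in range(n):
            end, _ = evolve_branch(space.index(10), t, Q, rng)
            freq[end] += 1
        tv = 0.5 * np.abs(freq / n - row).sum()
        assert tv < 0.04

    def test_root_state_outside_space_rejected(self):
        tree = kt.simulate_yule_tree(5, seed=1)
        with pytest.raises(ValueError):
            kt.simulate_counts(tree, kt.StateSpace(1, 8), kt.RateParams(), 9, seed=0)

    def test_branch_streams_are_independent(self):
        # distinct branch keys must give distinct streams
        r1 = _branch_rng(5, "t1#1").uniform(size=4)
        r2 = _branch_rng(5, "t1#2").uniform(size=4)
        r3 = _branch_rng(5, "t2#1").uniform(size=4)
        assert not np.allclose(r1, r2)
        assert not np.allclose(r1, r3)


class TestCladeRateTable:
    def test_no_between_spread_means_zero_icc(self):
        table, icc = kt.make_clade_rate_table(3, 18, sd_between=0.0, sd_within=0.5, seed=1)
        assert icc == 0.0
        assert len(table) == 54

    def test_equal_spreads_mean_half_icc(self):
        _, icc = kt.make_clade_rate_table(4, 5, sd_between=0.5, sd_within=0.5, seed=2)
        assert icc == pytest.approx(0.5)

    def test_unbalanced_paper_shaped_design(self):
        table, _ = kt.make_clade_rate_table(
            3, [43, 11, 1], sd_between=0.2, sd_within=0.5, seed=3
        )
        assert len(table) == 55
        res = kt.anova_oneway(np.log10(table["rate_myr"]), table["higher_taxon"])
        assert res["df"] == (2, 52)

    def test_rates_positive_and_log_normal_scale(self):
        table, _ = kt.make_clade_rate_table(5, 10, grand_mean_log10=-1.64,
                                            sd_between=0.3, sd_within=0.4, seed=4)
        assert (table["rate_myr"] > 0).all()
        assert 10 ** np.log10(table["rate_myr"]).mean() == pytest.approx(0.023, rel=0.7)


class TestBrownian:
    def test_zero_sigma_gives_zero_tips(self):
        tree = kt.simulate_yule_tree(10, seed=5)
        vals = kt.simulate_brownian(tree, 0.0, seed=6)
        assert (vals == 0).all()

    def test_cherry_variance_matches_depth(self):
        tree = kt.read_tree("(A:1,B:1);")
        sigma = 1.3
        draws = np.array(
            [kt.simulate_brownian(tree, sigma, seed=s)["A"] for s in range(5000)]
        )
        assert draws.var() == pytest.approx(sigma**2, rel=0.05)

    def test_star_tree_tips_uncorrelated(self):
        tree = kt.read_tree("(A:1,B:1,C:1,D:1);")
        a = np.array([kt.simulate_brownian(tree, 1.0, seed=s)["A"] for s in range(3000)])
        b = np.array([kt.simulate_brownian(tree, 1.0, seed=s)["B"] for s in range(3000)])
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.05
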