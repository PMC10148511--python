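"""Comparative methods against enumeration, closed-form and simulation oracles."""

import math

import numpy as np
import pytest

from conftest import brute_force_loglik, brute_force_marginals
from stoneoak.phylo import (
    MkModel,
    PhyloError,
    blomberg_k,
    brownian_asr,
    categorize_changes,
    count_transitions,
    fit_mk,
    marginal_asr,
    mk_loglik,
    read_newick,
    simulate_birth_death,
    simulate_tree_and_traits,
    write_newick,
)


class TestNewickIO:
    def test_small_tree(self):
        phy = read_newick("((A:1,B:1):1,C:2);")
        assert phy.n_tips == 3
        assert sum(1 for _ in phy.tree.preorder_internal_node_iter()) == 2

    def test_round_trip_random_trees(self):
        for s in range(25):
            phy = simulate_birth_death(12, 1.0, 0.2, seed=s)
            text = write_newick(phy)
            back = read_newick(text)
            assert sorted(back.tip_labels) == sorted(phy.tip_labels)
            a = {frozenset(l.taxon.label for l in nd.leaf_iter()):
                 nd.edge.length for nd in phy.tree.preorder_node_iter()}
            b = {frozenset(l.taxon.label for l in nd.leaf_iter()):
                 nd.edge.length for nd in back.tree.preorder_node_iter()}
            assert a.keys() == b.keys()
            for k in a:
                if a[k] is not None:
                    assert b[k] == pytest.approx(a[k], abs=1e-9)

    @pytest.mark.parametrize("bad", [";", "((A:1,B:1):1", "((A:1,A:1):1,C:2);"])
    def test_parse_errors(self, bad):
        with pytest.raises(PhyloError):
            read_newick(bad)


class TestMkLikelihood:
    def test_frozen_rates_identical_tips(self):
        phy = read_newick("(A:1,B:1);")
        m = MkModel(0.0, 0.0)
        assert math.exp(mk_loglik(phy, {"A": "AC", "B": "AC"}, m)) == pytest.approx(0.5)

    def test_frozen_rates_different_tips_impossible(self):
        phy = read_newick("(A:1,B:1);")
        assert mk_loglik(phy, {"A": "AC", "B": "ER"}, MkModel(0.0, 0.0)) == -math.inf

    def test_missing_tip_state_rejected(self):
        phy = read_newick("(A:1,B:1);")
        with pytest.raises(PhyloError, match="no state"):
            mk_loglik(phy, {"A": "AC"}, MkModel(0.1, 0.1))

    def test_pruning_equals_enumeration(self):
        rng = np.random.default_rng(5)
        for s in range(20):
            n = int(rng.integers(3, 7))
            phy = simulate_birth_death(n, 1.0, 0.1, seed=1000 + s)
            tips = {l: ("AC", "ER")[rng.integers(2)] for l in phy.tip_labels}
            if len(set(tips.values())) == 1:
                tips[phy.tip_labels[0]] = "ER" if tips[phy.tip_labels[0]] == "AC" else "AC"
            m = MkModel(rng.uniform(0.05, 2.0), rng.uniform(0.05, 2.0))
            assert mk_loglik(phy, tips, m) == pytest.approx(
                brute_force_loglik(phy, tips, m), abs=1e-12)


class TestMkFit:
    def test_rate_recovery(self):
        """Median ARD estimates within 25% of the generating rates."""
        q01s, q10s = [], []
        for s in range(40):
            sim = simulate_tree_and_traits(200, 1.0, 0.0, MkModel(0.5, 0.25), 0.5,
                                           seed=2000 + s)
            fit = fit_mk(sim.phylogeny, sim.tip_states, "ARD")
            q01s.append(fit.model.q01)
            q10s.append(fit.model.q10)
        assert abs(np.median(q01s) - 0.5) / 0.5 < 0.25
        assert abs(np.median(q10s) - 0.25) / 0.25 < 0.25

    def test_equal_rates_preferred_on_symmetric_data(self):
        wins = 0
        for s in range(15):
            sim = simulate_tree_and_traits(150, 1.0, 0.0, MkModel(0.4, 0.4), 0.5,
                                           seed=3000 + s)
            er = fit_mk(sim.phylogeny, sim.tip_states, "ER")
            ard = fit_mk(sim.phylogeny, sim.tip_states, "ARD")
            wins += er.aic <= ard.aic + 2
        assert wins >= 12

    def test_monomorphic_data_flagged(self):
        phy = simulate_birth_death(10, 1.0, 0.0, seed=1)
        tips = {l: "AC" for l in phy.tip_labels}
        fit = fit_mk(phy, tips, "ARD")
        assert fit.degenerate
        assert fit.model.q01 < 1e-6


class TestMarginalASR:
    def test_frozen_all_ac(self):
        phy = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {l: "AC" for l in "ABCD"}
        res = marginal_asr(phy, tips, MkModel(0.0, 0.0))
        for p in res.node_values.values():
            assert p[0] == pytest.approx(1.0)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for s in range(15):
            n = int(rng.integers(4, 7))
            phy = simulate_birth_death(n, 1.0, 0.1, seed=4000 + s)
            tips = {l: ("AC", "ER")[rng.integers(2)] for l in phy.tip_labels}
            m = MkModel(rng.uniform(0.05, 1.5), rng.uniform(0.05, 1.5))
            res = marginal_asr(phy, tips, m)
            brute = brute_force_marginals(phy, tips, m)
            for node, p in res.node_values.items():
                assert np.abs(p - brute[node]).max() < 1e-10

    def test_marginals_normalized(self):
        phy = simulate_birth_death(12, 1.0, 0.0, seed=2)
        rng = np.random.default_rng(0)
        tips = {l: ("AC", "ER")[rng.integers(2)] for l in phy.tip_labels}
        res = marginal_asr(phy, tips, MkModel(0.3, 0.2))
        for p in res.node_values.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_child_rotation(self):
        phy = read_newick("((A:0.4,B:0.6):0.5,(C:0.3,D:0.9):0.2);")
        rot = read_newick("(((D:0.9,C:0.3):0.2,(B:0.6,A:0.4):0.5));")
        # the rotated form re-roots identically: compare common clades
        tips = {"A": "AC", "B": "ER", "C": "AC", "D": "ER"}
        m = MkModel(0.4, 0.3)
        res1 = marginal_asr(phy, tips, m)

        phy2 = read_newick("((B:0.6,A:0.4):0.5,(D:0.9,C:0.3):0.2);")
        res2 = marginal_asr(phy2, tips, m)
        # same clades -> same marginals regardless of child order
        def by_clade(phy_, res_):
            out = {}
            for nd in phy_.tree.preorder_internal_node_iter():
                clade = frozenset(l.taxon.label for l in nd.leaf_iter())
                out[clade] = res_.node_values[nd.label]
            return out
        a, b = by_clade(phy, res1), by_clade(phy2, res2)
        for clade in a:
            assert np.allclose(a[clade], b[clade], atol=1e-12)

    def test_polytomy_rejected(self):
        phy = read_newick("(A:1,B:1,C:1);")
        with pytest.raises(PhyloError, match="bifurcating"):
            marginal_asr(phy, {l: "AC" for l in "ABC"}, MkModel(0.1, 0.1))


class TestTransitionCounts:
    def test_all_ac_zero(self):
        phy = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {l: "AC" for l in "ABCD"}
        res = marginal_asr(phy, tips, MkModel(1e-8, 1e-8))
        assert count_transitions(phy, res, tips) == {"AC->ER": 0, "ER->AC": 0}

    def test_two_independent_er_clades(self):
        """Two separate ER cherries under an AC backbone give two origins."""
        phy = read_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
        tips = dict(A="ER", B="ER", C="AC", D="AC", E="ER", F="ER", G="AC", H="AC")
        res = marginal_asr(phy, tips, MkModel(0.1, 0.1))
        counts = count_transitions(phy, res, tips)
        assert counts["AC->ER"] == 2
        assert counts["ER->AC"] == 0

    def test_map_counts_track_true_changes(self):
        """MAP-edge counts correlate with the realized jump counts."""
        est, true = [], []
        for s in range(60):
            sim = simulate_tree_and_traits(60, 1.0, 0.0, MkModel(0.25, 0.1), 0.5,
                                           seed=5000 + s)
            if len(set(sim.tip_states.values())) == 1:
                continue
            fit = fit_mk(sim.phylogeny, sim.tip_states, "ARD")
            res = marginal_asr(sim.phylogeny, sim.tip_states, fit.model)
            c = count_transitions(sim.phylogeny, res, sim.tip_states)
            est.append(c["AC->ER"] + c["ER->AC"])
            true.append(sim.true_changes["AC->ER"] + sim.true_changes["ER->AC"])
        assert len(est) > 30
        assert np.corrcoef(est, true)[0, 1] > 0.3

    def test_stochastic_mapping_close_to_map_in_clear_case(self):
        phy = read_newick(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
        tips = dict(A="ER", B="ER", C="AC", D="AC", E="ER", F="ER", G="AC", H="AC")
        # near-certain AC root so sampled histories agree on the direction
        model = MkModel(0.1, 0.1, root_prior=(0.99, 0.01))
        res = marginal_asr(phy, tips, model)
        sto = count_transitions(phy, res, tips, method="stochastic",
                                model=model, n_maps=200, seed=0)
        assert sto["AC->ER"] == pytest.approx(2.0, abs=0.75)
        assert sto["ER->AC"] < 1.0


class TestBlombergK:
    def test_four_tip_matrix_oracle(self):
        phy = read_newick("((A:1,B:1):0.5,(C:0.7,D:0.7):0.8);")
        vals = {"A": 1.0, "B": 1.4, "C": -0.2, "D": 0.3}
        C, labels = phy.vcv()
        x = np.array([vals[l] for l in labels])
        Ci = np.linalg.inv(C)
        one = np.ones(4)
        a = (one @ Ci @ x) / (one @ Ci @ one)
        d = x - a
        ratio = (d @ d) / (d @ Ci @ d)
        expected = (np.trace(C) - 4 / (one @ Ci @ one)) / 3
        res = blomberg_k(phy, vals, n_perm=0)
        assert res.K == pytest.approx(ratio / expected, abs=1e-10)

    def test_bm_calibration(self):
        ks = [blomberg_k(
            (sim := simulate_tree_and_traits(100, 1.0, 0.0, MkModel(0.1, 0.1),
                                             1.0, seed=6000 + s)).phylogeny,
            sim.tip_values, n_perm=0).K
            for s in range(60)]
        assert abs(np.mean(ks) - 1.0) <= 0.1

    def test_shuffling_destroys_signal(self):
        rng = np.random.default_rng(1)
        low = 0
        for s in range(30):
            sim = simulate_tree_and_traits(60, 1.0, 0.0, MkModel(0.1, 0.1), 1.0,
                                           seed=7000 + s)
            vals = np.array(list(sim.tip_values.values()))
            shuf = dict(zip(sim.tip_values, rng.permutation(vals)))
            low += blomberg_k(sim.phylogeny, shuf, n_perm=0).K < 1.0
        assert low >= 29

    def test_permutation_p_detects_bm_signal(self):
        sim = simulate_tree_and_traits(80, 1.0, 0.0, MkModel(0.1, 0.1), 1.0, seed=8000)
        res = blomberg_k(sim.phylogeny, sim.tip_values, n_perm=199, seed=0)
        assert res.p_value < 0.05

    def test_binary_trait_accepted(self):
        sim = simulate_tree_and_traits(40, 1.0, 0.0, MkModel(0.4, 0.2), 1.0, seed=8100)
        res = blomberg_k(sim.phylogeny, sim.tip_states, n_perm=0)
        assert res.K >= 0

    def test_star_tree_rejected(self):
        phy = read_newick("(A:1,B:1,C:1,D:1);")
        with pytest.raises(PhyloError, match="undefined"):
            blomberg_k(phy, {l: 1.0 for l in "ABCD"}, n_perm=0)


class TestBrownianASR:
    def test_two_tip_symmetric_root(self):
        phy = read_newick("(A:1,B:1);")
        res = brownian_asr(phy, {"A": 0.0, "B": 2.0})
        assert list(res.node_values.values())[0] == pytest.approx(1.0)

    def test_three_tip_gls_oracle(self):
        """Conditional-expectation formula built by hand from the covariances."""
        phy = read_newick("((A:1.0,B:2.0):0.5,C:3.0);")
        vals = {"A": 1.0, "B": 3.0, "C": -2.0}
        C, labels = phy.vcv()
        x = np.array([vals[l] for l in labels])
        Ci = np.linalg.inv(C)
        one = np.ones(3)
        mu = (one @ Ci @ x) / (one @ Ci @ one)
        # internal node above A,B sits at depth 0.5; its covariance with
        # A and B is 0.5, with C is 0
        c = np.array([0.5 if l in ("A", "B") else 0.0 for l in labels])
        expected = mu + c @ Ci @ (x - mu)
        res = brownian_asr(phy, vals)
        inner = [v for k, v in res.node_values.items() if k != phy.postorder[-1].label]
        assert inner[0] == pytest.approx(expected, abs=1e-10)
        root = res.node_values[phy.postorder[-1].label]
        assert root == pytest.approx(mu, abs=1e-10)

    def test_constant_values_propagate(self):
        phy = simulate_birth_death(10, 1.0, 0.0, seed=3)
        res = brownian_asr(phy, {l: 4.2 for l in phy.tip_labels})
        assert all(v == pytest.approx(4.2, abs=1e-9) for v in res.node_values.values())

    def test_root_equals_k_statistic_gls_mean(self):
        """Internal consistency: BM root = the GLS mean used inside K."""
        sim = simulate_tree_and_traits(30, 1.0, 0.0, MkModel(0.1, 0.1), 1.0, seed=9000)
        res = brownian_asr(sim.phylogeny, sim.tip_values)
        C, labels = sim.phylogeny.vcv()
        x = np.array([sim.tip_values[l] for l in labels])
        Ci = np.linalg.inv(C)
        one = np.ones(len(x))
        mu = (one @ Ci @ x) / (one @ Ci @ one)
        assert res.node_values[sim.phylogeny.postorder[-1].label] == pytest.approx(mu)


class TestCategorizeChanges:
    def _asr(self):
        phy = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        vals = {"A": 0.0, "B": 0.1, "C": 2.0, "D": 3.0}
        return phy, brownian_asr(phy, vals)

    def test_infinite_epsilon_all_same(self):
        phy, asr = self._asr()
        cats = categorize_changes(phy, asr, epsilon=math.inf)
        assert set(cats.values()) == {"same"}

    def test_zero_epsilon_no_same_without_exact_tie(self):
        phy, asr = self._asr()
        cats = categorize_changes(phy, asr, epsilon=0.0)
        assert "same" not in cats.values()

    def test_negative_epsilon_rejected(self):
        phy, asr = self._asr()
        with pytest.raises(PhyloError):
            categorize_changes(phy, asr, epsilon=-0.1)

    def test_monotone_trend_gives_majority_increase(self):
        # pectinate non-ultrametric tree; trait grows with tip depth
        phy = read_newick("(((((t1:1,t2:2):1,t3:3):1,t4:4):1,t5:5):1,t6:6);")
        depth = {}
        for nd in phy.tree.preorder_node_iter():
            p = nd.parent_node
            depth[id(nd)] = (depth[id(p)] if p else 0.0) + (nd.edge.length or 0.0)
        vals = {l.taxon.label: depth[id(l)] for l in phy.tree.leaf_node_iter()}
        res = brownian_asr(phy, vals)
        cats = categorize_changes(phy, res, epsilon=0.01)
        frac_inc = sum(c == "increase" for c in cats.values()) / len(cats)
        assert frac_inc > 0.5

    def test_divergent_clade_shift_detected(self):
        """A clade shifted upward reads as increase, the other as decrease."""
        phy = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        res = brownian_asr(phy, {"A": 0.0, "B": 0.0, "C": 10.0, "D": 10.0})
        cats = categorize_changes(phy, res, epsilon=0.05)
        assert cats == {"A": "decrease", "B": "decrease",
                        "C": "increase", "D": "increase"}


class TestSimulator:
    def test_seed_reproducibility(self):
        a = simulate_tree_and_traits(25, 1.0, 0.2, MkModel(0.3, 0.1), 0.7, seed=77)
        b = simulate_tree_and_traits(25, 1.0, 0.2, MkModel(0.3, 0.1), 0.7, seed=77)
        assert write_newick(a.phylogeny) == write_newick(b.phylogeny)
        assert a.tip_states == b.tip_states
        assert a.tip_values == b.tip_values
        assert a.true_changes == b.true_changes

    def test_bm_variance_scales_with_depth(self):
        """Across replicate trees, Var(tip - root) ~ sigma^2 * depth.

        One tip per tree so the deviations are independent across replicates.
        """
        sigma = 0.8
        scaled = []
        for s in range(150):
            sim = simulate_tree_and_traits(6, 2.0, 0.0, MkModel(0.0, 0.0), sigma,
                                           seed=11000 + s)
            phy = sim.phylogeny
            lf = next(phy.tree.leaf_node_iter())
            d, nd = 0.0, lf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            scaled.append(sim.tip_values[lf.taxon.label] / math.sqrt(d))
        assert np.var(scaled) == pytest.approx(sigma**2, rel=0.3)

    def test_invalid_rates_rejected(self):
        with pytest.raises(PhyloError):
            simulate_tree_and_traits(10, 0.5, 0.7, MkModel(0.1, 0.1), 1.0, seed=0)
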