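"""Mk fitting, stochastic character maps and regime Brownian rate models."""

import itertools

import numpy as np
import pytest
from scipy import stats

import wingleg as wl
from wingleg.rates import _transition_matrix
from wingleg.regimes import ALTRICIAL, PRECOCIAL


class TestFitMkEr:
    def test_all_precocial_boundary(self, yule20):
        states = {t: PRECOCIAL for t in yule20.tips}
        fit = wl.fit_mk_er(yule20, states)
        assert fit.q == 0.0
        assert fit.loglik == 0.0

    def test_grid_search_oracle_four_tips(self):
        """ML rate matches a 1e-4-grid brute force of the hand-written
        likelihood (one altricial tip among four, fixed precocial root)."""
        phy = wl.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = {"A": ALTRICIAL, "B": PRECOCIAL, "C": PRECOCIAL, "D": PRECOCIAL}
        fit = wl.fit_mk_er(phy, states)

        def ll(q):
            e = np.exp(-2.0 * q)
            same, diff = (1 + e) / 2, (1 - e) / 2
            P = np.array([[same, diff], [diff, same]])
            total = 0.0
            for u in (0, 1):  # parent of A, B
                for v in (0, 1):  # parent of C, D
                    total += (
                        P[1, u] * P[1, v] * P[u, 0] * P[u, 1] * P[v, 1] * P[v, 1]
                    )
            return np.log(total)

        grid = np.arange(1e-4, 5.0, 1e-4)
        vals = [ll(q) for q in grid]
        q_grid = grid[int(np.argmax(vals))]
        assert 1e-4 < q_grid < 4.9  # interior optimum, meaningful comparison
        assert fit.q == pytest.approx(q_grid, abs=2e-4)
        assert fit.loglik == pytest.approx(ll(fit.q), rel=1e-10)

    def test_two_tip_discordant_likelihood_shape(self, two_tip):
        """One tip in each state on a cherry: the ER likelihood increases
        monotonically in q (no interior optimum), so the fit reports the
        saturation plateau where log L -> 2 log(1/2)."""
        fit = wl.fit_mk_er(two_tip, {"A": ALTRICIAL, "B": PRECOCIAL})
        assert fit.loglik == pytest.approx(2 * np.log(0.5), abs=1e-6)

    def test_rate_scales_inversely_with_branch_lengths(self):
        phy1 = wl.simulate_tree(30, seed=8, tree_height=40.0)
        phy2 = wl.parse_newick(phy1.to_newick())
        # double every branch length by rescaling the height
        phy2.edge_length *= 2
        phy2.depth *= 2
        rmap = wl.simulate_regimes(phy1, 0.05, PRECOCIAL, seed=9)
        states = rmap.tip_states
        if len(set(states.values())) < 2:
            pytest.skip("degenerate simulation draw")
        q1 = wl.fit_mk_er(phy1, states).q
        q2 = wl.fit_mk_er(phy2, states).q
        assert q2 == pytest.approx(q1 / 2, rel=1e-4)

    def test_unknown_state_rejected(self, two_tip):
        with pytest.raises(ValueError, match="state"):
            wl.fit_mk_er(two_tip, {"A": "semialtricial", "B": PRECOCIAL})


class TestSampleSimmap:
    def test_zero_rate_concordant_tips(self, yule20):
        states = {t: PRECOCIAL for t in yule20.tips}
        mk = wl.fit_mk_er(yule20, states)
        maps = wl.sample_simmap(yule20, states, mk, n_maps=3, seed=1)
        assert all(m.n_transitions() == 0 for m in maps)

    def test_zero_rate_discordant_tips_impossible(self, two_tip):
        mk = wl.MkFit(q=0.0, loglik=0.0)
        with pytest.raises(ValueError, match="rate is 0"):
            wl.sample_simmap(two_tip, {"A": ALTRICIAL, "B": PRECOCIAL}, mk)

    def test_tip_segments_match_observed_states(self, yule20):
        rmap_true = wl.simulate_regimes(yule20, 0.03, PRECOCIAL, seed=2)
        states = rmap_true.tip_states
        if len(set(states.values())) < 2:
            pytest.skip("degenerate simulation draw")
        mk = wl.fit_mk_er(yule20, states)
        for m in wl.sample_simmap(yule20, states, mk, n_maps=5, seed=3):
            assert m.tip_states == states

    def test_conservation_on_sampled_maps(self, yule20):
        rmap_true = wl.simulate_regimes(yule20, 0.03, PRECOCIAL, seed=4)
        states = rmap_true.tip_states
        mk = wl.MkFit(q=0.02, loglik=0.0)
        C = wl.vcv(yule20).C
        for m in wl.sample_simmap(yule20, states, mk, n_maps=4, seed=5):
            paths = wl.regime_path_lengths(m, yule20)
            np.testing.assert_allclose(
                paths.B_altricial + paths.B_precocial, C, atol=1e-9
            )

    def test_node_marginals_match_enumeration(self):
        """Sampled node-state frequencies match exact conditional marginals
        computed by brute-force enumeration over all internal assignments."""
        phy = wl.parse_newick("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);")
        states = {
            "A": ALTRICIAL,
            "B": PRECOCIAL,
            "C": ALTRICIAL,
            "D": PRECOCIAL,
            "E": PRECOCIAL,
        }
        q = 0.3
        idx = {ALTRICIAL: 0, PRECOCIAL: 1}
        internal = [n for n in range(phy.n_nodes) if not phy.is_tip(n)]
        tip_state = {
            n: idx[states[phy.tip_label(n)]] for n in phy.tip_ids
        }

        # enumeration oracle: joint probability of every internal assignment
        probs = {}
        for combo in itertools.product((0, 1), repeat=len(internal)):
            assign = dict(zip(internal, combo))
            if assign[0] != idx[PRECOCIAL]:  # fixed precocial root
                continue
            assign.update(tip_state)
            pr = 1.0
            for nid in range(1, phy.n_nodes):
                P = _transition_matrix(q, float(phy.edge_length[nid]))
                pr *= P[assign[int(phy.parent[nid])], assign[nid]]
            probs[combo] = pr
        total = sum(probs.values())
        marg = {
            node: sum(p for c, p in probs.items() if c[k] == 0) / total
            for k, node in enumerate(internal)
        }

        mk = wl.MkFit(q=q, loglik=0.0)
        n_maps = 2000
        maps = wl.sample_simmap(phy, states, mk, n_maps=n_maps, seed=7)
        for node in internal:
            freq = np.mean([m.node_state(node) == ALTRICIAL for m in maps])
            se = np.sqrt(max(marg[node] * (1 - marg[node]), 1e-9) / n_maps)
            assert abs(freq - marg[node]) < 3.5 * se + 1e-9


class TestRegimePathLengths:
    def test_all_precocial_map(self, yule20):
        rmap = wl.simulate_regimes(yule20, 0.0, PRECOCIAL, seed=0)
        paths = wl.regime_path_lengths(rmap, yule20)
        np.testing.assert_allclose(paths.B_altricial, 0.0)
        np.testing.assert_allclose(paths.B_precocial, wl.vcv(yule20).C)

    def test_single_midpoint_transition_by_hand(self):
        phy = wl.parse_newick("(A:2,B:2);")
        a_id, b_id = phy.tip_ids
        segments = [[] for _ in range(phy.n_nodes)]
        segments[a_id] = [(PRECOCIAL, 1.0), (ALTRICIAL, 1.0)]
        segments[b_id] = [(PRECOCIAL, 2.0)]
        rmap = wl.RegimeMap(phy=phy, segments=segments, root_state=PRECOCIAL)
        paths = wl.regime_path_lengths(rmap, phy)
        tips = list(phy.tips)
        ia, ib = tips.index("A"), tips.index("B")
        assert paths.B_altricial[ia, ia] == pytest.approx(1.0)
        assert paths.B_altricial[ib, ib] == pytest.approx(0.0)
        assert paths.B_altricial[ia, ib] == pytest.approx(0.0)
        assert paths.B_precocial[ia, ia] == pytest.approx(1.0)
        assert paths.B_precocial[ib, ib] == pytest.approx(2.0)


class TestFitBm:
    def test_constant_trait_zero_rate(self, yule20):
        A = wl.vcv(yule20)
        fit = wl.fit_bm_single(np.full(20, 1.7), A)
        assert fit.sigma2 == 0.0

    def test_three_tip_closed_form(self, three_tip):
        A = wl.vcv(three_tip)
        y = np.array([0.1, 0.5, -0.4])
        fit = wl.fit_bm_single(y, A)
        Ci = np.linalg.inv(A.C)
        ones = np.ones(3)
        mu = (ones @ Ci @ y) / (ones @ Ci @ ones)
        s2 = (y - mu) @ Ci @ (y - mu) / 3
        ll = -0.5 * (
            3 * np.log(2 * np.pi * s2) + np.linalg.slogdet(A.C)[1] + 3
        )
        assert fit.mu == pytest.approx(mu, rel=1e-10)
        assert fit.sigma2 == pytest.approx(s2, rel=1e-10)
        assert fit.loglik == pytest.approx(ll, rel=1e-10)

    def test_degenerate_regime_reduces_to_single(self, yule20):
        A = wl.vcv(yule20)
        rmap = wl.simulate_regimes(yule20, 0.0, PRECOCIAL, seed=0)
        paths = wl.regime_path_lengths(rmap, yule20)
        rng = np.random.default_rng(11)
        y = np.linalg.cholesky(2e-4 * A.C + 1e-12 * np.eye(20)) @ rng.standard_normal(
            20
        )
        single = wl.fit_bm_single(y, A)
        two = wl.fit_bm_two_rate(y, paths)
        assert two.loglik == pytest.approx(single.loglik, abs=1e-6)
        assert two.sigma2_precocial == pytest.approx(single.sigma2, rel=1e-4)


class TestLikelihoodRatio:
    def test_equal_likelihoods(self):
        f0 = wl.RateFit("single", 1.0, None, None, 0.0, -10.0, 2)
        f1 = wl.RateFit("two_rate", None, 1.0, 1.0, 0.0, -10.0, 3)
        lam, p = wl.likelihood_ratio_test(f0, f1)
        assert lam == 0.0
        assert p == 1.0

    def test_chi_square_tail_value(self):
        f0 = wl.RateFit("single", 1.0, None, None, 0.0, 0.0, 2)
        f1 = wl.RateFit("two_rate", None, 1.0, 1.0, 0.0, 10.8276 / 2, 3)
        lam, p = wl.likelihood_ratio_test(f0, f1)
        assert lam == pytest.approx(10.8276)
        assert p == pytest.approx(stats.chi2.sf(10.8276, 1), rel=1e-12)
        assert p == pytest.approx(0.001, rel=5e-3)

    def test_optimizer_failure_detected(self):
        f0 = wl.RateFit("single", 1.0, None, None, 0.0, -5.0, 2)
        f1 = wl.RateFit("two_rate", None, 1.0, 1.0, 0.0, -6.0, 3)
        with pytest.raises(ValueError, match="optimizer"):
            wl.likelihood_ratio_test(f0, f1)


class TestAncestralScores:
    def test_star_tree_internal_mean(self):
        phy = wl.parse_newick("(A:3,B:3,C:3,D:3);")
        y = np.array([1.0, 2.0, 3.0, 6.0])
        table = wl.ancestral_scores(phy, y)
        root = table.loc[~table["is_tip"]]
        assert len(root) == 1
        assert root["estimate"].iloc[0] == pytest.approx(3.0)

    def test_two_tip_symmetry(self, two_tip):
        table = wl.ancestral_scores(two_tip, np.array([0.0, 4.0]))
        assert table.loc[~table["is_tip"], "estimate"].iloc[0] == pytest.approx(2.0)

    def test_matches_joint_gaussian_conditioning(self):
        """Internal estimates equal the conditional mean of the joint
        tip+node Brownian Gaussian, built by brute-force covariance."""
        phy = wl.parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
        y = np.array([0.2, -0.1, 0.7, 1.5])  # order A, B, C, D below
        y = y[: phy.n_tips]
        table = wl.ancestral_scores(phy, dict_to_series(y, phy))
        A = wl.vcv(phy)
        mu = wl.phylo_mean(A, table.loc[table["is_tip"], "estimate"].to_numpy())
        tip_pos = {phy.tip_label(int(t)): k for k, t in enumerate(phy.tip_ids)}
        yv = np.array([y[i] for i in range(phy.n_tips)])
        for nid in range(phy.n_nodes):
            if phy.is_tip(nid):
                continue
            # covariance of node value with each tip = depth of their MRCA
            cvec = np.zeros(phy.n_tips)
            for t in phy.tip_ids:
                anc_t = set(_ancestors(phy, int(t)))
                anc_n = set(_ancestors(phy, nid))
                mrca = max(anc_t & anc_n, key=lambda x: phy.depth[x])
                cvec[tip_pos[phy.tip_label(int(t))]] = phy.depth[mrca]
            expected = mu + cvec @ np.linalg.solve(A.C, yv - mu)
            assert table.loc[nid, "estimate"] == pytest.approx(expected, rel=1e-9)


def _ancestors(phy, nid):
    out = []
    while nid != -1:
        out.append(nid)
        nid = int(phy.parent[nid])
    return out


def dict_to_series(y, phy):
    import pandas as pd

    return pd.Series(np.asarray(y, dtype=float), index=phy.tips)
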