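"""Two-state gain/loss model: transition kernel, likelihood, posteriors,
event calls — checked against closed forms and exhaustive enumeration."""

import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm
from skbio import TreeNode

from vartig.gainloss import (
    AncestralStateMap,
    GainLossParams,
    PhyleticPattern,
    ancestral_posteriors,
    call_events,
    discrete_gamma_rates,
    family_loglik,
    fit_params,
    transition_matrix,
)
from vartig.simulate import SimConfig, simulate_gene_content, simulate_species_tree
from vartig.trees import tree_arrays


def brute_force_loglik(tree, pat, params):
    """Exhaustive enumeration over all internal-state assignments."""
    ta = tree_arrays(tree)
    rg = params.g0 * discrete_gamma_rates(params.alpha_gain, params.K)
    rl = params.l0 * discrete_gamma_rates(params.alpha_loss, params.K)
    internal = [n for n in range(ta.n_nodes) if ta.children[n]]
    total = 0.0
    for g in rg:
        for l in rl:
            pi = np.array([l, g]) / (g + l)
            for assign in itertools.product([0, 1], repeat=len(internal)):
                st_map = dict(zip(internal, assign))
                for i in range(ta.n_leaves):
                    st_map[i] = pat[i]
                p = pi[st_map[ta.root]]
                for n in range(ta.n_nodes):
                    if ta.parent[n] >= 0:
                        P = transition_matrix(g, l, ta.length[n])
                        p *= P[st_map[ta.parent[n]], st_map[n]]
                total += p / (len(rg) * len(rl))
    return np.log(total)


def brute_force_posteriors(tree, pat, params):
    ta = tree_arrays(tree)
    rg = params.g0 * discrete_gamma_rates(params.alpha_gain, params.K)
    rl = params.l0 * discrete_gamma_rates(params.alpha_loss, params.K)
    internal = [n for n in range(ta.n_nodes) if ta.children[n]]
    marg = np.zeros(ta.n_nodes)
    total = 0.0
    for g in rg:
        for l in rl:
            pi = np.array([l, g]) / (g + l)
            for assign in itertools.product([0, 1], repeat=len(internal)):
                st_map = dict(zip(internal, assign))
                for i in range(ta.n_leaves):
                    st_map[i] = pat[i]
                p = pi[st_map[ta.root]]
                for n in range(ta.n_nodes):
                    if ta.parent[n] >= 0:
                        P = transition_matrix(g, l, ta.length[n])
                        p *= P[st_map[ta.parent[n]], st_map[n]]
                total += p
                for n in range(ta.n_nodes):
                    if st_map[n] == 1:
                        marg[n] += p
    return marg / total


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        assert np.allclose(transition_matrix(2.0, 3.0, 0.0), np.eye(2))

    def test_long_time_reaches_stationary(self):
        P = transition_matrix(1.0, 1.0, 1e6)
        assert abs(P[0, 1] - 0.5) < 1e-12

    def test_closed_form_matches_matrix_exponential(self):
        Q = np.array([[-2.0, 2.0], [1.0, -1.0]])
        assert np.allclose(transition_matrix(2.0, 1.0, 0.5), expm(Q * 0.5), atol=1e-12)
        assert transition_matrix(2.0, 1.0, 0.5)[0, 1] == pytest.approx(
            (2.0 / 3.0) * (1 - np.exp(-1.5)), abs=1e-12
        )

    def test_rows_sum_to_one(self):
        P = transition_matrix(0.7, 0.2, 1.3)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(-1.0, 1.0, 1.0)

    @given(
        st.floats(0.01, 5.0), st.floats(0.01, 5.0),
        st.floats(0.0, 3.0), st.floats(0.0, 3.0),
    )
    @settings(max_examples=60, derandomize=True)
    def test_chapman_kolmogorov(self, g, l, t1, t2):
        lhs = transition_matrix(g, l, t1) @ transition_matrix(g, l, t2)
        rhs = transition_matrix(g, l, t1 + t2)
        assert np.abs(lhs - rhs).max() < 1e-10


class TestFamilyLoglik:
    def test_zero_length_branch_reduces_to_root_prior(self):
        tree = TreeNode.read(io.StringIO("(A:0.0)root;"))
        params = GainLossParams(g0=0.4, l0=0.6, K=1)
        ll = family_loglik(tree, {"A": 1}, params)
        assert ll == pytest.approx(np.log(0.4 / (0.4 + 0.6)), abs=1e-12)

    def test_likelihood_is_a_probability(self):
        tree = simulate_species_tree(5, 2)
        params = GainLossParams()
        ll = family_loglik(tree, np.array([1, 0, 1, 1, 0]), params)
        assert 0 < np.exp(ll) < 1

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 7))
            tree = simulate_species_tree(n, int(rng.integers(10_000)))
            pat = rng.integers(0, 2, n)
            params = GainLossParams(
                g0=float(rng.uniform(0.2, 2)), l0=float(rng.uniform(0.2, 2)),
                K=int(rng.integers(1, 3)),
            )
            assert family_loglik(tree, pat, params) == pytest.approx(
                brute_force_loglik(tree, pat, params), abs=1e-8
            )

    def test_leaf_mismatch_rejected(self):
        tree = simulate_species_tree(4, 1)
        with pytest.raises(ValueError):
            family_loglik(tree, {"G01": 1}, GainLossParams())


class TestPosteriors:
    def test_leaves_return_observed_states(self):
        tree = simulate_species_tree(5, 3)
        pat = np.array([1, 0, 1, 0, 1])
        post = ancestral_posteriors(tree, pat[None, :], GainLossParams())
        assert np.array_equal(post.probs[0, :5], pat)

    def test_mirror_symmetric_tree_gives_symmetric_posteriors(self):
        tree = TreeNode.read(io.StringIO("((a:1.0,b:1.0)u:0.5,(c:1.0,d:1.0)v:0.5)root;"))
        post = ancestral_posteriors(tree, {"a": 1, "b": 0, "c": 0, "d": 1},
                                    GainLossParams(K=2))
        pu = post.get("fam0", "u")
        pv = post.get("fam0", "v")
        assert pu == pytest.approx(pv, abs=1e-12)

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 7))
            tree = simulate_species_tree(n, int(rng.integers(10_000)))
            pat = rng.integers(0, 2, n)
            params = GainLossParams(
                g0=float(rng.uniform(0.2, 2)), l0=float(rng.uniform(0.2, 2)),
                K=int(rng.integers(1, 3)),
            )
            post = ancestral_posteriors(tree, pat[None, :], params)
            oracle = brute_force_posteriors(tree, pat, params)
            assert np.abs(post.probs[0] - oracle).max() < 1e-8


class TestCallEvents:
    def _chain_map(self, p_root, p_mid):
        tree = TreeNode.read(io.StringIO("((A:1.0)mid:1.0)root;"))
        post = AncestralStateMap(
            families=["f"], node_names=["A", "mid", "root"],
            probs=np.array([[1.0, p_mid, p_root]]),
        )
        return tree, post

    def test_gain_called_above_half(self):
        tree, post = self._chain_map(p_root=0.1, p_mid=0.7)
        calls = call_events(post, tree)
        gain = [c for c in calls if c.child == "mid"]
        assert gain and gain[0].type == "gain"
        assert gain[0].delta == pytest.approx(0.6)

    def test_no_call_below_threshold(self):
        tree, post = self._chain_map(p_root=0.75, p_mid=0.30)
        assert not [c for c in call_events(post, tree) if c.child == "mid"]

    def test_loss_to_absent_leaf(self):
        tree, post = self._chain_map(p_root=0.95, p_mid=0.95)
        post.probs[0, 0] = 0.0  # leaf observed absent
        calls = [c for c in call_events(post, tree) if c.child == "A"]
        assert calls and calls[0].type == "loss"
        assert calls[0].delta == pytest.approx(-0.95)

    def test_exactly_half_makes_no_call(self):
        tree, post = self._chain_map(p_root=0.25, p_mid=0.75)
        assert not [c for c in call_events(post, tree) if c.child == "mid"]

    def test_antisymmetry_under_label_swap(self):
        # flipping presence/absence turns every gain into a loss on the
        # same branch (stationary root prior makes the model symmetric)
        tree = simulate_species_tree(6, 8)
        rng = np.random.default_rng(0)
        pat = rng.integers(0, 2, (30, 6))
        params = GainLossParams(g0=0.5, l0=1.0)
        swapped = GainLossParams(g0=1.0, l0=0.5)
        calls = call_events(ancestral_posteriors(tree, pat, params), tree)
        anti = call_events(ancestral_posteriors(tree, 1 - pat, swapped), tree)
        key = lambda cs: sorted((c.family, c.parent, c.child, c.type) for c in cs)
        flipped = [(f, p, c, "gain" if t == "loss" else "loss") for f, p, c, t in key(anti)]
        assert key(calls) == sorted(flipped)


@pytest.fixture(scope="module")
def small_fit():
    tree = simulate_species_tree(10, 42)
    cfg = SimConfig(n_genomes=10, n_families=300, gain_scale=0.5,
                    loss_scale=1.0, seed=7)
    pattern, _ = simulate_gene_content(tree, cfg)
    return tree, pattern, fit_params(pattern, tree, K=2)


class TestFitParams:
    def test_recovers_rate_scales_roughly(self, small_fit):
        _, _, p = small_fit
        assert 0.2 < p.g0 < 1.2
        assert 0.4 < p.l0 < 2.2

    def test_refit_is_a_fixed_point(self, small_fit):
        from vartig.gainloss import loglik_families
        from vartig.trees import tree_arrays

        tree, pattern, p = small_fit
        ta = tree_arrays(tree)
        order = [pattern.genomes.index(n) for n in ta.leaf_names]
        mat = pattern.presence[:, order]
        ll1 = loglik_families(ta, mat, p).sum()
        p2 = fit_params(pattern, tree, K=2)
        ll2 = loglik_families(ta, mat, p2).sum()
        assert abs(ll1 - ll2) < 1e-6

    def test_label_swap_swaps_rates(self, small_fit):
        tree, pattern, p = small_fit
        swapped = PhyleticPattern(pattern.families, pattern.genomes,
                                  1 - pattern.presence)
        q = fit_params(swapped, tree, K=2)
        assert q.g0 == pytest.approx(p.l0, rel=0.1)
        assert q.l0 == pytest.approx(p.g0, rel=0.1)

    def test_degenerate_pattern_warns(self):
        tree = simulate_species_tree(4, 1)
        pattern = PhyleticPattern(["f1"], [t.name for t in tree.tips()],
                                  np.ones((1, 4), dtype=int))
        with pytest.warns(UserWarning):
            fit_params(pattern, tree)
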