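"""MMCA probability-tree update, fixed points and the spectral threshold."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lacsnet as L
from lacsnet.mmca import awareness_steady_state

from .conftest import random_mmca_state


def uniform_hetero(n, gamma=1.0, alpha=0.5):
    return L.NodeHeterogeneity.homogeneous(n, gamma, alpha)


def path4_star_net():
    """US node 0 with four awareness neighbours (star), same contagion layer."""
    return L.couple_layers(nx.star_graph(4), mode="identical")


class TestUnawarePersistence:
    def make_state(self, p_aware_neighbors):
        # node 0 is the hub; neighbours 1..4 carry the given aware probability
        p_as = np.zeros(5)
        p_as[1:] = p_aware_neighbors
        return L.MMCAState(p_us=1 - p_as, p_as=p_as, p_ai=np.zeros(5))

    def test_below_threshold_stays_unaware(self):
        net = path4_star_net()
        state = self.make_state([1, 0, 0, 0])  # aware fraction 0.25
        r = L.unaware_persistence(state, net, np.full(5, 0.5))
        assert r[0] == 1.0

    def test_tie_triggers_awareness(self):
        # H(0) = 0: fraction exactly at threshold means the node turns aware
        net = path4_star_net()
        state = self.make_state([1, 0, 0, 0])
        r = L.unaware_persistence(state, net, np.full(5, 0.25))
        assert r[0] == 0.0

    def test_zero_threshold_is_spontaneous(self):
        # alpha = 0 with zero aware mass still gives H(0) = 0 -> r = 0;
        # the formula is applied literally
        net = path4_star_net()
        state = self.make_state([0, 0, 0, 0])
        r = L.unaware_persistence(state, net, np.zeros(5))
        assert r[0] == 0.0

    def test_isolated_node_never_alerted(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        net = L.complete_layers(g, g)
        state = L.MMCAState(
            p_us=np.array([0.0, 0.0, 1.0]),
            p_as=np.array([1.0, 1.0, 0.0]),
            p_ai=np.zeros(3),
        )
        r = L.unaware_persistence(state, net, np.zeros(3))
        assert r[2] == 1.0


class TestEscapeProbabilities:
    def test_no_infected_mass_gives_one(self):
        net = path4_star_net()
        state = L.MMCAState(p_us=np.ones(5), p_as=np.zeros(5), p_ai=np.zeros(5))
        q_a, q_u = L.escape_probabilities(
            state, net, L.ModelParams(0.9, 0.5, 0.5), uniform_hetero(5, gamma=0.5)
        )
        assert np.allclose(q_a, 1.0) and np.allclose(q_u, 1.0)

    def test_single_infected_neighbor(self):
        net = L.couple_layers(nx.path_graph(2), mode="identical")
        state = L.MMCAState(
            p_us=np.array([1.0, 0.0]), p_as=np.zeros(2), p_ai=np.array([0.0, 1.0])
        )
        q_a, q_u = L.escape_probabilities(
            state, net, L.ModelParams(0.3, 0.5, 0.5), uniform_hetero(2, gamma=0.5)
        )
        assert q_u[0] == pytest.approx(0.7)
        assert q_a[0] == pytest.approx(0.85)

    def test_two_half_infected_neighbors(self):
        net = path4_star_net()
        p_ai = np.array([0.0, 0.5, 0.5, 0.0, 0.0])
        state = L.MMCAState(p_us=1 - p_ai, p_as=np.zeros(5), p_ai=p_ai)
        q_a, q_u = L.escape_probabilities(
            state, net, L.ModelParams(0.2, 0.5, 0.5), uniform_hetero(5, gamma=1.0)
        )
        assert q_u[0] == pytest.approx(0.81)
        assert q_a[0] == pytest.approx(0.81)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_aware_escape_never_below_unaware(self, seed):
        rng = np.random.default_rng(seed)
        net = L.couple_layers(
            L.generate_er_layer(30, 4.0, seed=int(rng.integers(2**31))),
            mode="identical",
        )
        state = random_mmca_state(rng, 30)
        hetero = L.NodeHeterogeneity(gamma=rng.random(30), alpha=rng.random(30))
        q_a, q_u = L.escape_probabilities(
            state, net, L.ModelParams(float(rng.random()), 0.5, 0.5), hetero
        )
        assert (q_a >= q_u - 1e-15).all()


class TestStepAndConservation:
    def test_probability_conserved_over_random_draws(self, er_multiplex_small, rng):
        net = er_multiplex_small
        n = net.n_nodes
        worst = 0.0
        for _ in range(1000):
            state = random_mmca_state(rng, n)
            params = L.ModelParams(*rng.random(3))
            hetero = L.NodeHeterogeneity(gamma=rng.random(n), alpha=rng.random(n))
            new = L.mmca_step(state, net, params, hetero)
            total = new.p_us + new.p_as + new.p_ai
            worst = max(worst, float(np.abs(total - 1).max()))
            assert new.p_us.min() >= 0 and new.p_as.min() >= 0 and new.p_ai.min() >= 0
        assert worst < 1e-12

    def test_recover_and_forget_simultaneously(self):
        net = path4_star_net()
        state = L.MMCAState(p_us=np.zeros(5), p_as=np.zeros(5), p_ai=np.ones(5))
        new = L.mmca_step(state, net, L.ModelParams(0.5, 1.0, 1.0), uniform_hetero(5))
        assert np.allclose(new.p_us, 1.0)

    def test_infection_decays_geometrically_without_transmission(self):
        net = path4_star_net()
        p_ai = np.full(5, 0.6)
        state = L.MMCAState(p_us=np.zeros(5), p_as=1 - p_ai, p_ai=p_ai)
        mu = 0.3
        new = L.mmca_step(state, net, L.ModelParams(0.0, mu, 0.0), uniform_hetero(5))
        assert np.allclose(new.p_ai, p_ai * (1 - mu))


class TestFixedPoint:
    def test_no_transmission_eliminates_infection(self, er_multiplex_small):
        fp = L.mmca_fixed_point(
            er_multiplex_small,
            L.ModelParams(0.0, 0.8, 0.3),
            uniform_hetero(er_multiplex_small.n_nodes),
            seed=0,
        )
        assert fp.converged
        assert fp.rho_I == pytest.approx(0.0, abs=1e-6)

    def test_no_recovery_absorbs_to_all_infected(self, er_multiplex_small):
        net = er_multiplex_small
        assert nx.is_connected(net.layer_graph("contagion"))
        fp = L.mmca_fixed_point(
            net, L.ModelParams(0.6, 0.0, 0.3), uniform_hetero(net.n_nodes), seed=0,
            tol=1e-10,
        )
        assert fp.rho_I == pytest.approx(1.0, abs=1e-4)

    def test_fixed_point_rho_monotone_in_beta(self, er_multiplex_small):
        net = er_multiplex_small
        hetero = L.assign_heterogeneity(net, "degree", "degree", "positive")
        rhos = [
            L.mmca_fixed_point(
                net, L.ModelParams(b, 0.8, 0.3), hetero, seed=0
            ).rho_I
            for b in np.linspace(0.1, 0.9, 9)
        ]
        assert all(b >= a - 1e-6 for a, b in zip(rhos, rhos[1:]))


class TestSpectralThreshold:
    def test_S_reduces_to_B_without_awareness(self, er_multiplex_small):
        net = er_multiplex_small
        n = net.n_nodes
        hetero = L.NodeHeterogeneity(gamma=np.random.default_rng(0).random(n),
                                     alpha=np.full(n, 0.5))
        S = L.build_S_matrix(net, hetero, np.zeros(n))
        assert (S != net.B).nnz == 0
        S = L.build_S_matrix(net, uniform_hetero(n, gamma=1.0), np.ones(n) * 0.7)
        assert (S != net.B).nnz == 0

    def test_S_vanishes_under_full_protection(self, er_multiplex_small):
        net = er_multiplex_small
        n = net.n_nodes
        S = L.build_S_matrix(net, uniform_hetero(n, gamma=0.0), np.ones(n))
        assert abs(S).sum() == 0.0

    @pytest.mark.parametrize("mu", [0.2, 0.8])
    def test_cycle_closed_form(self, mu):
        net = L.couple_layers(nx.cycle_graph(40), mode="identical")
        beta_c = L.epidemic_threshold(
            net,
            L.ModelParams(0.0, mu, 0.3),
            uniform_hetero(net.n_nodes, alpha=0.9),
            infected_fraction=0.0,
        )
        assert beta_c == pytest.approx(mu / 2.0, abs=1e-10)

    def test_complete_graph_closed_form(self):
        n = 17
        net = L.couple_layers(nx.complete_graph(n), mode="identical")
        beta_c = L.epidemic_threshold(
            net,
            L.ModelParams(0.0, 0.8, 0.3),
            uniform_hetero(n, alpha=0.9),
            infected_fraction=0.0,
        )
        assert beta_c == pytest.approx(0.8 / (n - 1), abs=1e-10)

    def test_uniform_awareness_scalar_factorisation(self, er_multiplex_small):
        # S = (1 - (1-g) a) B, so Lambda_max factorises; cross-check densely
        net = er_multiplex_small
        n = net.n_nodes
        a, g = 0.6, 0.3
        hetero = uniform_hetero(n, gamma=g)
        S = L.build_S_matrix(net, hetero, np.full(n, a))
        lam_dense = np.linalg.eigvals(S.toarray()).real.max()
        lam_B = np.linalg.eigvals(net.B.toarray()).real.max()
        assert lam_dense == pytest.approx((1 - (1 - g) * a) * lam_B, rel=1e-10)

    def test_threshold_uses_awareness_steady_state(self, er_multiplex_small):
        net = er_multiplex_small
        n = net.n_nodes
        params = L.ModelParams(0.0, 0.8, 0.3)
        hetero = L.assign_heterogeneity(net, "degree", "degree", "negative")
        pA = awareness_steady_state(net, params, hetero, seed=0)
        assert pA.min() >= 0 and pA.max() <= 1
        factor = 1 - (1 - hetero.gamma) * pA
        lam = np.linalg.eigvals(L.build_S_matrix(net, hetero, pA).toarray()).real.max()
        beta_c = L.epidemic_threshold(net, params, hetero, seed=0)
        assert beta_c == pytest.approx(params.mu / lam, rel=1e-8)
        # protection can only raise the threshold above the bare-SIS value
        lam_B = np.linalg.eigvals(net.B.toarray()).real.max()
        assert beta_c >= params.mu / lam_B - 1e-12
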