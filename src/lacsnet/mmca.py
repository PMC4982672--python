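"""Microscopic Markov Chain Approach (MMCA) engine.

Discrete-time per-node probability iteration for the coupled
awareness-epidemic (UAU-SIS) dynamics, under the standard assumption that
neighbour contributions are independent.  Each node carries a probability
triple (p_US, p_AS, p_AI) over the three admissible states — unaware
susceptible, aware susceptible, aware infected — which the probability-tree
update maps forward while conserving per-node probability exactly.

The epidemic threshold follows from linearising the infected equation
around the disease-free state: beta_c^U = mu / Lambda_max(S), with
s_ji = [1 - (1 - gamma_i) p_i^A] b_ji built from the contagion adjacency B
and the awareness-only steady state p^A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import eigsh

from .heterogeneity import NodeHeterogeneity
from .multiplex import MultiplexNetwork

__all__ = [
    "ModelParams",
    "MMCAState",
    "FixedPointResult",
    "mmca_initial_state",
    "unaware_persistence",
    "escape_probabilities",
    "mmca_step",
    "mmca_fixed_point",
    "awareness_steady_state",
    "build_S_matrix",
    "epidemic_threshold",
]

_DENSE_EIG_CUTOFF = 500


@dataclass(frozen=True)
class ModelParams:
    """Global transition probabilities of the coupled dynamics.

    beta_U : infection probability per infectious contact for an unaware node
             (aware nodes use gamma_i * beta_U).
    mu     : recovery probability per step.
    delta  : awareness-loss probability per step.
    """

    beta_U: float
    mu: float
    delta: float

    def __post_init__(self):
        for name in ("beta_U", "mu", "delta"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class MMCAState:
    """Per-node probability triple at iteration ``t``; rows sum to 1."""

    p_us: np.ndarray
    p_as: np.ndarray
    p_ai: np.ndarray
    t: int = 0

    @property
    def p_aware(self) -> np.ndarray:
        return self.p_as + self.p_ai

    @property
    def rho_I(self) -> float:
        """Mean infected probability over nodes."""
        return float(self.p_ai.mean())

    @property
    def rho_A(self) -> float:
        """Mean aware probability over nodes."""
        return float(self.p_aware.mean())

    def validate(self, tol: float = 1e-12) -> None:
        total = self.p_us + self.p_as + self.p_ai
        if np.abs(total - 1.0).max() > tol:
            raise ValueError("per-node probabilities do not sum to 1")
        for p in (self.p_us, self.p_as, self.p_ai):
            if p.min() < -tol or p.max() > 1 + tol:
                raise ValueError("probability outside [0, 1]")


def mmca_initial_state(
    n: int, infected_fraction: float = 0.2, seed: int | None = None
) -> MMCAState:
    """Deterministic seed state: a random ceil(f*n) subset starts AI (p=1).

    Seeding mirrors the stochastic engine — whole nodes are made infected
    (and hence aware), rather than smearing the fraction over all nodes.
    ``infected_fraction=0`` gives the all-unaware-susceptible state.
    """
    if not 0 <= infected_fraction <= 1:
        raise ValueError("infected_fraction outside [0, 1]")
    p_ai = np.zeros(n)
    n_seed = min(n, int(np.ceil(infected_fraction * n)))
    if n_seed:
        idx = np.random.default_rng(seed).choice(n, size=n_seed, replace=False)
        p_ai[idx] = 1.0
    return MMCAState(p_us=1.0 - p_ai, p_as=np.zeros(n), p_ai=p_ai, t=0)


def unaware_persistence(
    state: MMCAState, net: MultiplexNetwork, alpha: np.ndarray
) -> np.ndarray:
    """r_i = H(alpha_i - sum_j a_ji p_j^A / k_i): stay-unaware indicator.

    The Heaviside convention H(0) = 0 means a node whose aware-neighbour
    fraction exactly equals its threshold *does* become aware.  Nodes with
    no awareness-layer neighbours cannot be alerted (r = 1) regardless of
    alpha.
    """
    k = net.degrees("awareness").astype(np.float64)
    aware_mass = net.A @ state.p_aware
    r = np.ones(net.n_nodes)
    nz = k > 0
    # compare alpha*k with the neighbour mass to avoid dividing by k
    r[nz] = (alpha[nz] * k[nz] - aware_mass[nz] > 0).astype(np.float64)
    return r


def _neighbor_products(adj: sparse.csr_array, edge_factors: np.ndarray) -> np.ndarray:
    """Row-wise product of per-edge factors; empty rows give 1."""
    indptr = adj.indptr
    out = np.ones(adj.shape[0])
    nonempty = np.flatnonzero(np.diff(indptr) > 0)
    if nonempty.size:
        out[nonempty] = np.multiply.reduceat(edge_factors, indptr[nonempty])
    return out


def escape_probabilities(
    state: MMCAState,
    net: MultiplexNetwork,
    params: ModelParams,
    hetero: NodeHeterogeneity,
) -> tuple[np.ndarray, np.ndarray]:
    """(q_A, q_U): per-node probability of not being infected this step.

    q_i^U = prod_j (1 - b_ji p_j^AI beta_U), and q_i^A replaces beta_U with
    node i's reduced rate gamma_i * beta_U, so q_A >= q_U elementwise.
    """
    B = net.B
    p_nbr = state.p_ai[B.indices]
    q_u = _neighbor_products(B, 1.0 - params.beta_U * p_nbr)
    gamma_rows = np.repeat(hetero.gamma, np.diff(B.indptr))
    q_a = _neighbor_products(B, 1.0 - gamma_rows * params.beta_U * p_nbr)
    return q_a, q_u


def mmca_step(
    state: MMCAState,
    net: MultiplexNetwork,
    params: ModelParams,
    hetero: NodeHeterogeneity,
) -> MMCAState:
    """One parallel update of the probability tree.

    p_US' = p_AI d m     + p_US r q_U         + p_AS d q_U
    p_AS' = p_AI m (1-d) + p_US (1-r) q_A     + p_AS (1-d) q_A
    p_AI' = p_AI (1-m)   + p_US [(1-r)(1-q_A) + r (1-q_U)]
                         + p_AS [d (1-q_U) + (1-d)(1-q_A)]

    with d = delta, m = mu.  Infection imposes awareness (no unaware
    infected state), and an unaware node that crosses its threshold is
    already protected (q_A) within the same step.
    """
    d, m = params.delta, params.mu
    r = unaware_persistence(state, net, hetero.alpha)
    q_a, q_u = escape_probabilities(state, net, params, hetero)
    p_us, p_as, p_ai = state.p_us, state.p_as, state.p_ai

    new_us = p_ai * d * m + p_us * r * q_u + p_as * d * q_u
    new_as = p_ai * m * (1 - d) + p_us * (1 - r) * q_a + p_as * (1 - d) * q_a
    new_ai = (
        p_ai * (1 - m)
        + p_as * (d * (1 - q_u) + (1 - d) * (1 - q_a))
        + p_us * ((1 - r) * (1 - q_a) + r * (1 - q_u))
    )
    new = MMCAState(p_us=new_us, p_as=new_as, p_ai=new_ai, t=state.t + 1)
    new.validate(tol=1e-9)
    return new


@dataclass(frozen=True)
class FixedPointResult:
    """Steady state of the MMCA iteration with convergence diagnostics.

    ``oscillating`` marks a detected period-2 cycle (possible because the
    threshold rule makes the map discontinuous); the reported state is then
    the average of the two cycle points.
    """

    state: MMCAState
    iterations: int
    converged: bool
    oscillating: bool = False

    @property
    def rho_I(self) -> float:
        return self.state.rho_I

    @property
    def rho_A(self) -> float:
        return self.state.rho_A


def _state_distance(a: MMCAState, b: MMCAState) -> float:
    return max(
        float(np.abs(a.p_us - b.p_us).max()),
        float(np.abs(a.p_as - b.p_as).max()),
        float(np.abs(a.p_ai - b.p_ai).max()),
    )


def _average_states(a: MMCAState, b: MMCAState) -> MMCAState:
    return MMCAState(
        p_us=(a.p_us + b.p_us) / 2,
        p_as=(a.p_as + b.p_as) / 2,
        p_ai=(a.p_ai + b.p_ai) / 2,
        t=b.t,
    )


def mmca_fixed_point(
    net: MultiplexNetwork,
    params: ModelParams,
    hetero: NodeHeterogeneity,
    init: MMCAState | None = None,
    infected_fraction: float = 0.2,
    seed: int | None = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> FixedPointResult:
    """Iterate :func:`mmca_step` to a fixed point (or period-2 cycle)."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    state = init if init is not None else mmca_initial_state(
        net.n_nodes, infected_fraction, seed
    )
    prev = None
    for it in range(1, max_iter + 1):
        new = mmca_step(state, net, params, hetero)
        if _state_distance(new, state) < tol:
            return FixedPointResult(state=new, iterations=it, converged=True)
        if prev is not None and _state_distance(new, prev) < tol:
            return FixedPointResult(
                state=_average_states(state, new),
                iterations=it,
                converged=True,
                oscillating=True,
            )
        prev, state = state, new
    return FixedPointResult(state=state, iterations=max_iter, converged=False)


def awareness_steady_state(
    net: MultiplexNetwork,
    params: ModelParams,
    hetero: NodeHeterogeneity,
    infected_fraction: float = 0.2,
    seed: int | None = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Steady-state aware probability p^A with the epidemic switched off.

    This is the awareness-only reduction of the coupled update (q_A = q_U
    = 1, i.e. beta_U = 0) run from the same seeded initial condition as the
    experiments; it supplies the p^A entering the threshold matrix S in the
    vanishing-prevalence limit.
    """
    fp = mmca_fixed_point(
        net,
        ModelParams(beta_U=0.0, mu=params.mu, delta=params.delta),
        hetero,
        infected_fraction=infected_fraction,
        seed=seed,
        tol=tol,
        max_iter=max_iter,
    )
    return fp.state.p_aware


def build_S_matrix(
    net: MultiplexNetwork, hetero: NodeHeterogeneity, p_aware: np.ndarray
) -> sparse.csr_array:
    """S with s_ji = [1 - (1 - gamma_i) p_i^A] b_ji (column-scaled B)."""
    p_aware = np.asarray(p_aware, dtype=np.float64)
    if p_aware.min(initial=0.0) < 0 or p_aware.max(initial=0.0) > 1:
        raise ValueError("p_aware outside [0, 1]")
    factor = 1.0 - (1.0 - hetero.gamma) * p_aware
    return sparse.csr_array(net.B @ sparse.diags(factor))


def _largest_eigenvalue(B: sparse.csr_array, factor: np.ndarray) -> float:
    """Lambda_max of S = B diag(factor) for factor >= 0.

    S is similar to the symmetric diag(sqrt f) B diag(sqrt f), so the
    spectrum is real and the Perron root can be taken from a symmetric
    eigensolver; dense below N=500, Lanczos above.
    """
    n = B.shape[0]
    sq = sparse.diags(np.sqrt(np.clip(factor, 0.0, None)))
    sym = sq @ B @ sq
    if n < _DENSE_EIG_CUTOFF:
        return float(np.linalg.eigvalsh(sym.toarray()).max())
    return float(eigsh(sparse.csr_matrix(sym), k=1, which="LA",
                       return_eigenvectors=False, tol=1e-10)[0])


def epidemic_threshold(
    net: MultiplexNetwork,
    params: ModelParams,
    hetero: NodeHeterogeneity,
    infected_fraction: float = 0.2,
    seed: int | None = 0,
    tol: float = 1e-10,
) -> float:
    """Spectral epidemic threshold beta_c^U = mu / Lambda_max(S).

    Returns ``inf`` when Lambda_max <= 0 (no epidemic possible at any
    infectivity, e.g. an edgeless contagion layer under full protection).
    """
    if net.B.nnz == 0:
        raise ValueError("contagion layer has no edges")
    p_aware = awareness_steady_state(
        net, params, hetero, infected_fraction=infected_fraction, seed=seed
    )
    factor = 1.0 - (1.0 - hetero.gamma) * p_aware
    lam = _largest_eigenvalue(net.B, factor)
    if lam <= tol:
        return float("inf")
    return params.mu / lam
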