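"""Stochastic engine: synchronous discrete-time simulation of the coupled dynamics.

Every node is in exactly one of three states — unaware susceptible (US),
aware susceptible (AS) or aware infected (AI); an unaware infected state
does not exist because infection imposes awareness.  All transitions in a
step are evaluated from the time-t configuration (parallel updating), with
the same tie and edge-case conventions as the deterministic MMCA engine:

* a US node becomes aware when its aware-neighbour fraction is >= alpha_i
  (ties alert, mirroring H(0) = 0), or when it gets infected this step;
* a node that is aware at time t — or crosses its awareness threshold this
  step — is infected with the reduced probability gamma_i * beta_U, while
  an AS node that loses awareness this step is exposed at the full beta_U;
* an AI node recovers with probability mu and simultaneously forgets with
  probability delta: both -> US, recovery alone -> AS, otherwise it stays
  AI (awareness cannot be shed while infected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heterogeneity import NodeHeterogeneity
from .mmca import ModelParams
from .multiplex import MultiplexNetwork

__all__ = [
    "US",
    "AS",
    "AI",
    "MCState",
    "mc_init",
    "mc_step",
    "mc_run",
    "mc_stationary",
    "mc_threshold_scan",
    "StationaryResult",
    "ThresholdScanResult",
]

US, AS, AI = 0, 1, 2


@dataclass
class MCState:
    """Discrete node states plus the stream of randomness driving them."""

    states: np.ndarray  # int8 in {US, AS, AI}
    t: int
    rng: np.random.Generator

    @property
    def rho_I(self) -> float:
        return float(np.mean(self.states == AI))

    @property
    def rho_A(self) -> float:
        return float(np.mean(self.states != US))

    def validate(self) -> None:
        if not np.isin(self.states, (US, AS, AI)).all():
            raise ValueError("invalid node state label")


def mc_init(
    net: MultiplexNetwork, infected_fraction: float = 0.2, seed: int | None = None
) -> MCState:
    """Seed a run: a uniformly random ceil(f*N) subset starts AI, the rest US."""
    if not 0 < infected_fraction <= 1:
        raise ValueError("infected_fraction must be in (0, 1]")
    n = net.n_nodes
    rng = np.random.default_rng(seed)
    n_seed = min(n, int(np.ceil(infected_fraction * n)))
    states = np.full(n, US, dtype=np.int8)
    states[rng.choice(n, size=n_seed, replace=False)] = AI
    return MCState(states=states, t=0, rng=rng)


def mc_step(
    mc: MCState,
    net: MultiplexNetwork,
    params: ModelParams,
    hetero: NodeHeterogeneity,
) -> MCState:
    """Advance one synchronous step; consumes randomness from ``mc.rng``."""
    states = mc.states
    rng = mc.rng
    n = states.size
    aware = states != US
    infected = states == AI

    # threshold rule on the awareness layer (evaluated at time t)
    k = net.degrees("awareness").astype(np.float64)
    aware_neighbors = net.A @ aware.astype(np.float64)
    crosses = np.zeros(n, dtype=bool)
    nz = k > 0  # isolated awareness-layer nodes can only be alerted by infection
    crosses[nz] = aware_neighbors[nz] >= hetero.alpha[nz] * k[nz]

    # contagion layer exposure (counts of infectious neighbours at time t)
    m_inf = net.B @ infected.astype(np.float64)
    forget = rng.random(n) < params.delta
    recover = rng.random(n) < params.mu
    u_inf = rng.random(n)

    # effective per-contact probability for susceptible nodes this step
    reduced = ((states == US) & crosses) | ((states == AS) & ~forget)
    beta_eff = np.where(reduced, hetero.gamma * params.beta_U, params.beta_U)
    p_infect = 1.0 - (1.0 - beta_eff) ** m_inf
    gets_infected = (states != AI) & (u_inf < p_infect)

    new = np.empty(n, dtype=np.int8)
    # susceptibles
    was_us = states == US
    was_as = states == AS
    new[was_us & ~gets_infected & crosses] = AS
    new[was_us & ~gets_infected & ~crosses] = US
    new[was_as & ~gets_infected & ~forget] = AS
    new[was_as & ~gets_infected & forget] = US
    new[gets_infected] = AI
    # infected
    was_ai = states == AI
    new[was_ai & ~recover] = AI
    new[was_ai & recover & ~forget] = AS
    new[was_ai & recover & forget] = US
    return MCState(states=new, t=mc.t + 1, rng=rng)


def mc_run(
    net: MultiplexNetwork,
    params: ModelParams,
    hetero: NodeHeterogeneity,
    n_steps: int = 1000,
    infected_fraction: float = 0.2,
    seed: int | None = None,
    check_states: bool = False,
) -> pd.DataFrame:
    """Single trajectory; returns a tidy (t, rho_I, rho_A) frame."""
    mc = mc_init(net, infected_fraction, seed)
    rows = [(0, mc.rho_I, mc.rho_A)]
    for _ in range(n_steps):
        mc = mc_step(mc, net, params, hetero)
        if check_states:
            mc.validate()
        rows.append((mc.t, mc.rho_I, mc.rho_A))
    return pd.DataFrame(rows, columns=["t", "rho_I", "rho_A"])


@dataclass(frozen=True)
class StationaryResult:
    """Stationary fractions averaged over time windows and independent runs."""

    rho_I: float
    rho_A: float
    se_I: float
    se_A: float
    run_rho_I: np.ndarray
    run_rho_A: np.ndarray
    n_extinct: int
    node_freq_I: np.ndarray | None = None
    node_freq_A: np.ndarray | None = None


def mc_stationary(
    net: MultiplexNetwork,
    params: ModelParams,
    hetero: NodeHeterogeneity,
    n_steps: int = 1000,
    burn_in: int = 500,
    n_runs: int = 50,
    infected_fraction: float = 0.2,
    seed: int | None = 0,
    collect_node_freq: bool = False,
) -> StationaryResult:
    """Stationary rho_I, rho_A: time average after burn-in, over n_runs runs.

    Runs in which the epidemic goes extinct contribute their (near-zero)
    window averages unchanged — no resampling.  Standard errors are over
    the independent runs.  With ``collect_node_freq`` the per-node occupation
    frequencies of the infected and aware states over the same window are
    returned (for class profiles).
    """
    if burn_in >= n_steps:
        raise ValueError("burn_in must be smaller than n_steps")
    child_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    window = n_steps - burn_in
    run_I = np.empty(n_runs)
    run_A = np.empty(n_runs)
    n_extinct = 0
    freq_I = np.zeros(net.n_nodes) if collect_node_freq else None
    freq_A = np.zeros(net.n_nodes) if collect_node_freq else None
    for r, ss in enumerate(child_seeds):
        mc = mc_init(net, infected_fraction, np.random.default_rng(ss))
        acc_I = acc_A = 0.0
        for step in range(n_steps):
            mc = mc_step(mc, net, params, hetero)
            if step >= burn_in:
                acc_I += mc.rho_I
                acc_A += mc.rho_A
                if collect_node_freq:
                    freq_I += mc.states == AI
                    freq_A += mc.states != US
        run_I[r] = acc_I / window
        run_A[r] = acc_A / window
        if mc.rho_I == 0.0:
            n_extinct += 1
    if collect_node_freq:
        freq_I /= window * n_runs
        freq_A /= window * n_runs
    return StationaryResult(
        rho_I=float(run_I.mean()),
        rho_A=float(run_A.mean()),
        se_I=float(run_I.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else float("nan"),
        se_A=float(run_A.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else float("nan"),
        run_rho_I=run_I,
        run_rho_A=run_A,
        n_extinct=n_extinct,
        node_freq_I=freq_I,
        node_freq_A=freq_A,
    )


@dataclass(frozen=True)
class ThresholdScanResult:
    """Onset of a nonzero stationary epidemic along an infectivity grid."""

    beta_c: float
    onset_found: bool
    beta_grid: np.ndarray
    rho_I: np.ndarray
    grid_resolution: float


def mc_threshold_scan(
    net: MultiplexNetwork,
    beta_grid,
    mu: float,
    delta: float,
    hetero: NodeHeterogeneity,
    onset_criterion: float = 0.005,
    n_steps: int = 1000,
    burn_in: int = 500,
    n_runs: int = 50,
    infected_fraction: float = 0.2,
    seed: int | None = 0,
) -> ThresholdScanResult:
    """Smallest grid beta with stationary rho_I above the onset criterion.

    The grid spacing is the resolution (and the uncertainty) of the
    estimate; if no grid point crosses the criterion the threshold is
    reported as +inf with ``onset_found=False``.
    """
    beta_grid = np.asarray(sorted(beta_grid), dtype=np.float64)
    rho = np.empty(beta_grid.size)
    for i, beta in enumerate(beta_grid):
        res = mc_stationary(
            net,
            ModelParams(beta_U=float(beta), mu=mu, delta=delta),
            hetero,
            n_steps=n_steps,
            burn_in=burn_in,
            n_runs=n_runs,
            infected_fraction=infected_fraction,
            seed=seed,
        )
        rho[i] = res.rho_I
    above = np.flatnonzero(rho > onset_criterion)
    resolution = float(np.diff(beta_grid).max()) if beta_grid.size > 1 else float("nan")
    if above.size:
        return ThresholdScanResult(
            beta_c=float(beta_grid[above[0]]),
            onset_found=True,
            beta_grid=beta_grid,
            rho_I=rho,
            grid_resolution=resolution,
        )
    return ThresholdScanResult(
        beta_c=float("inf"),
        onset_found=False,
        beta_grid=beta_grid,
        rho_I=rho,
        grid_resolution=resolution,
    )
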