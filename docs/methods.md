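# Model and methods

## The coupled dynamics

One population of `N` individuals lives on two aligned simple, unweighted,
undirected graphs: an awareness layer `A = {a_ij}` and a contagion layer
`B = {b_ij}`. Node states are US (unaware susceptible), AS (aware
susceptible) and AI (aware infected); an unaware-infected state does not
exist because infection immediately makes a node aware. Per time step, with
parallel updating:

* **Awareness (UAU with a local threshold).** An unaware node `i` becomes
  aware when the fraction of its awareness-layer neighbours that are aware
  reaches its local threshold `α_i`, or when it is infected this step. An
  aware node forgets with probability `δ`, unless it is (or becomes)
  infected.
* **Epidemic (SIS).** A susceptible node is infected independently by each
  infectious contagion-layer neighbour, with per-contact probability `β^U`
  if it faces the step unaware and `β_i^A = γ_i β^U` if aware; infected
  nodes recover with probability `μ`.

Tie and edge-case conventions, applied identically in both engines:

* The threshold comparison uses the Heaviside convention `H(0) = 0` in the
  stay-unaware indicator `r_i = H(α_i − Σ_j a_ji p_j^A / k_i)`: a fraction
  *exactly equal* to `α_i` already triggers awareness. A literal corollary
  is that `α_i = 0` nodes turn aware spontaneously (fraction 0 ≥ threshold
  0); we keep the formula literal rather than special-casing it, and note
  that min–max-scaled `α` assigns 0 to some node by construction.
* Nodes with no awareness-layer neighbours can never be alerted socially
  (`r_i = 1` regardless of `α_i`); infection remains their only route to
  awareness.
* Within a step, transitions compose as a probability tree: an AI node
  recovers *and* forgets with probability `μδ` (→ US), recovers only with
  `μ(1 − δ)` (→ AS), and otherwise stays AI — an infected node cannot shed
  awareness while infected. An AS node that forgets this step is exposed at
  the full rate `β^U`; a US node that crosses its threshold this step is
  already protected (`γ_i β^U`) in the same step.

The AI → AS branch carries probability `μ(1 − δ)` and enters the aware-
susceptible balance as `p_i^AI μ(1 − δ)`; this is the unique assignment
under which the three per-node update equations sum to one identically,
which the test suite asserts to 1e−12 over random states and parameters.

## Heterogeneity assignment

Importance is measured per layer by the node degree or by the k-core
(k-shell) index — the largest `k` such that the node survives iterative
pruning of all nodes with degree ≤ `k` (isolated nodes get 0; computed via
the standard linear-time decomposition in `networkx`, and cross-checked in
the tests against a brute-force pruning oracle). Min–max scaling of the
chosen measure on the **contagion** layer gives `γ_i ∈ [0, 1]`; on the
**awareness** layer it gives `α_i` under the positive model, `1 − scaled`
under the negative model, or i.i.d. `U[0, 1]` draws under the random model.
Random-model thresholds are drawn once per experiment from a recorded seed
and shared across all Monte Carlo replicates — replication uncertainty then
reflects the dynamics, not the parameter draw.

Degenerate extrema (a regular layer, where max = min) would divide by
zero; we assign the neutral value 0.5 to every node and emit a warning,
since a homogeneous layer is outside the heterogeneity premise but useful
in closed-form tests.

## MMCA engine and the spectral threshold

The MMCA iterates per-node probability triples under the independence
approximation: the escape probabilities are products over contagion-layer
neighbours, `q_i^U = Π_j (1 − b_ji p_j^AI β^U)` and likewise with
`γ_i β^U` for `q_i^A`. Fixed points are sought by direct iteration with
convergence tolerance `1e−8` (max per-node change) and `max_iter = 10^4`.
Because the Heaviside makes the map discontinuous, parallel updating can
settle on a period-2 cycle; the solver detects two-step recurrence and
returns the cycle average, flagged `oscillating`.

The epidemic threshold is `β_c^U = μ / Λ_max(S)` with
`s_ji = [1 − (1 − γ_i) p_i^A] b_ji`. The awareness profile `p^A` entering
`S` is the steady state of the awareness-only reduction of the update
(`β^U = 0`, so infection decays and the threshold cascade equilibrates),
run from the same seeded initial condition as the experiments — the
cascade's fixed point genuinely depends on the initial aware set, so the
initialisation is part of the threshold's definition here. `S` is similar
to the symmetric `√F B √F` (`F = diag` of the column factors), so its
spectrum is real; we use a dense symmetric eigensolver below `N = 500` and
Lanczos (`eigsh`, tolerance 1e−10) above. `Λ_max ≤ 0` (e.g. full
protection) reports the threshold as `+∞`.

## Monte Carlo engine

Synchronous updating with all coin flips taken against the time-`t`
configuration; one step costs `O(N + |E|)` using sparse matrix-vector
products for the aware-neighbour and infectious-neighbour counts. A run
starts from a uniformly random `⌈fN⌉`-subset in state AI (default
`f = 0.2`), with counterparts automatically aware. Stationary fractions
are time averages after a burn-in, averaged over independent runs seeded
through `numpy.random.SeedSequence` spawning, so identical inputs and seed
reproduce trajectories bit for bit. Runs that go extinct contribute their
(near-zero) averages unchanged. Defaults: `n_steps = 1000`,
`burn_in = 500`, `n_runs = 50`, onset criterion `ρ^I > 0.005` for
threshold scans, with the grid spacing reported as the onset uncertainty.

## Synthetic networks

* **Scale-free layers** come from the configuration model with degrees
  drawn from a discrete truncated power law `P(k) ∝ k^−exponent` on
  `[k_cut, n−1]`. An integer cutoff cannot realise an arbitrary mean
  degree (at exponent 3, `k_cut = 3` gives ⟨k⟩ ≈ 5.1 and `k_cut = 4` gives
  ≈ 7.1), so each node's cutoff is drawn from the two bracketing integers
  with the mixing probability that makes the expected mean exact; an
  odd-sum degree sequence gets one randomly chosen degree incremented.
  Self-loops and parallel edges are deleted, not rewired — the distortion
  is `O(⟨k⟩²/n)`. Realised mean degree lands within a few percent of
  target at `n = 10^3`–`10^4`, and the degree-tail exponent matches a
  discrete maximum-likelihood fit to ±0.3.
* **Erdős–Rényi layers** are `G(n, p)` with `p = ⟨k⟩/(n − 1)`.
* **Coupling.** `identical` mode uses one graph for both layers (maximal
  positive interlayer correlation); `independent` mode pairs two separately
  generated layers after a random node-label permutation of the second,
  which destroys interlayer degree correlation (empirical Spearman ≈ 0).

What the generators deliberately do not emulate: degree–degree
assortativity within a layer, clustering beyond what the configuration
model produces, community structure, and any partial (between 0 and
maximal) interlayer correlation. Conclusions drawn from passing tests
therefore speak to these idealised topologies plus the one bundled
empirical-network pathway (the multiplex edge-list reader and layer
completion), not to structured real contact networks in general.

## Study configuration and scaling

The comparative sweeps (tests and `scripts/acceptance.py`) run the model's
reference conditions — `μ = 0.8`, `δ = 0.3`, 20 % initially infected,
correlated scale-free multiplex with exponent 3 and ⟨k⟩ = 6 — at
`N = 10^3`, the package's scaled-down default for the four-measure-case
comparison (network size is a config knob; the phenomenology of interest
is already stable at this size). The infectivity grid is dense (step 0.02)
through the onset region `β ≤ 0.32` with 10 Monte Carlo runs per point,
and coarse (5 points, 5 runs) up to `β = 0.9`; each run uses 400 steps
with a 200-step burn-in. Robustness is operationalised as the max-over-β
pairwise gap between the three model curves `ρ^I(β)`; onsets use the
0.005 criterion at the grid resolution of 0.02.

At these conditions the package reproduces, and its acceptance checks
assert, the model's characteristic orderings: with the k-core measure on
the contagion layer the three threshold models give nearly identical
epidemics (small robustness gap) and a larger final size than the degree
measure; with degree on both layers the negative model erupts first, with
degree on the contagion layer and k-core on the awareness layer the
positive model erupts first; and at high infectivity the infection
probability is non-decreasing across k-shells.

## Known limitations

* The MMCA inherits the independent-neighbour approximation; its threshold
  is known to undershoot simulation when the degree measure drives the
  contagion-layer heterogeneity, and agreement is best with the k-core
  measure — the cross-engine tests bound the discrepancy rather than
  eliminate it.
* The threshold cascade's dependence on the initial aware set means
  `epidemic_threshold` is defined relative to an initialisation; the
  default mirrors the experiments' 20 % seeding.
* Only two layers enter the dynamics; the edge-list reader parses
  arbitrarily many, but extra layers are ignored by the model.
* Weighted or directed layers and asynchronous (e.g. Gillespie) updating
  are out of scope.
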