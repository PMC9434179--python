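"""The stochastic Wright-Fisher engine.

Each generation applies two kernels to the class-count vector:

* **mutation** — RES cells mutate to WT or to one of the n COM classes, each
  destination at rate μ, via one multinomial draw over the RES count (stay
  probability 1 - (n+1)μ).  If second mutations are allowed, each COM class
  loses Binomial(count, μ) cells to CR.  At most one mutational step per cell
  per generation: COM cells created this generation cannot also convert to CR.
  WT and CR never mutate further.
* **reproduction** — the next generation is one multinomial draw of size N
  with class probabilities proportional to count × fitness (selection plus
  drift in a single step).

Two execution paths share these kernels: :func:`run_replicate` records a full
single-replicate trajectory from its own seeded generator, and
:func:`run_batch` advances many replicates at once as vectorized arrays
(used by the experiment grids, where only final states are needed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    FitnessScheme,
    PopulationState,
    SimulationParams,
    build_fitness,
    initial_state,
    validate_params,
)

__all__ = [
    "Trajectory",
    "mutate_step",
    "selection_drift_step",
    "run_replicate",
    "run_batch",
    "replicate_rng",
]


@dataclass(frozen=True)
class Trajectory:
    """Ordered population states for generations 0..G plus their parameters."""

    params: SimulationParams
    states: list[PopulationState]

    def counts_matrix(self) -> np.ndarray:
        """(G+1, n_classes) integer array of class counts over time."""
        return np.stack([s.counts for s in self.states])

    @property
    def final(self) -> PopulationState:
        return self.states[-1]


def _mutation_pvals(params: SimulationParams) -> np.ndarray:
    """Destination probabilities for a RES cell: [stay, COM(1)..COM(n), WT]."""
    mu = params.mu
    pvals = np.empty(params.n + 2)
    pvals[0] = 1.0 - (params.n + 1) * mu
    pvals[1:] = mu
    return pvals


def _mutate_counts(
    counts: np.ndarray, params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Mutation kernel on a batch of count rows (R, n_classes)."""
    if params.mu == 0.0:
        return counts.copy()
    out = counts.copy()
    res = counts[:, params.RES]
    pvals = _mutation_pvals(params)
    # one multinomial per row: RES -> stay / COM(1..n) / WT
    moved = rng.multinomial(res, pvals)  # (R, n+2)
    out[:, params.RES] = moved[:, 0]
    if params.n > 0:
        out[:, params.com_slice] += moved[:, 1:-1]
    out[:, params.WT] += moved[:, -1]
    if params.allow_second_mutation and params.n > 0:
        # conversions drawn from the *pre-mutation* COM counts
        conv = rng.binomial(counts[:, params.com_slice], params.mu)
        out[:, params.com_slice] -= conv
        out[:, params.CR] += conv.sum(axis=1)
    return out


def _reproduce_counts(
    counts: np.ndarray,
    fitness: FitnessScheme,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Selection+drift kernel on a batch of count rows."""
    weights = counts * fitness.w
    total = weights.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("all-zero fitness weight vector")
    q = weights / total
    return rng.multinomial(params.N, q)


def mutate_step(
    state: PopulationState, params: SimulationParams, rng: np.random.Generator
) -> PopulationState:
    """Apply one generation of mutation; the generation index is unchanged."""
    new = _mutate_counts(state.counts[None, :], params, rng)[0]
    return PopulationState(state.generation, new)


def selection_drift_step(
    state: PopulationState,
    fitness: FitnessScheme,
    params: SimulationParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Multinomial reproduction weighted by fitness; increments the generation."""
    new = _reproduce_counts(state.counts[None, :], fitness, params, rng)[0]
    return PopulationState(state.generation + 1, new)


def replicate_rng(master_seed: int, replicate_index: int) -> np.random.Generator:
    """Independent generator for one replicate of a seeded run set."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(replicate_index,))
    )


def run_replicate(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> Trajectory:
    """Run one replicate from the all-RES state and record every generation.

    Bit-reproducible given the seed: with ``rng=None`` the generator is built
    from ``params.seed``.
    """
    validate_params(params)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fitness = build_fitness(params)
    state = initial_state(params)
    states = [state]
    for _ in range(params.G):
        if params.event_order == "mutate_first":
            state = mutate_step(state, params, rng)
            state = selection_drift_step(state, fitness, params, rng)
        else:
            state = selection_drift_step(state, fitness, params, rng)
            state = mutate_step(state, params, rng)
        state.check(params)
        states.append(state)
    return Trajectory(params=params, states=states)


def run_batch(
    params: SimulationParams,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance ``n_replicates`` independent replicates and return final counts.

    Returns an ``(n_replicates, n_classes)`` integer array of generation-G
    class counts.  All replicates share ``rng``; seed the generator per grid
    cell for reproducible grids.
    """
    validate_params(params)
    fitness = build_fitness(params)
    counts = np.zeros((n_replicates, params.n_classes), dtype=np.int64)
    counts[:, params.RES] = params.N
    for _ in range(params.G):
        if params.event_order == "mutate_first":
            counts = _mutate_counts(counts, params, rng)
            counts = _reproduce_counts(counts, fitness, params, rng)
        else:
            counts = _reproduce_counts(counts, fitness, params, rng)
            counts = _mutate_counts(counts, params, rng)
    assert (counts.sum(axis=1) == params.N).all()
    return counts
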