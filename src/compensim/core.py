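"""Domain types shared by the simulator, the analytic model and the experiment grids.

The model follows a haploid bacterial population after a costly resistance
mutation has fixed and the environment has reverted, so that the resistance
allele now carries a fitness cost ``c``.  Four kinds of genotype exist:

* ``RES`` — the resistant ancestor, fitness ``1 - c``;
* ``COM(i)`` — resistant plus the i-th of ``n`` possible compensatory
  mutations.  A compensatory mutation removes a proportion ``p`` of the cost
  (fitness ``1 - c*(1 - p)``), unless target ``i`` is one of the ``m`` fully
  compensating targets, in which case fitness is 1;
* ``WT`` — reverted to wild type, fitness 1;
* ``CR`` — compensated reversal: a compensatory mutation followed by a
  reversal mutation, fitness 1 (equal to wild type).

Counts are stored in a fixed-length integer vector of ``n + 3`` classes,
indexed ``RES`` = 0, ``COM(i)`` = i for i = 1..n, ``WT`` = n+1, ``CR`` = n+2.
The ``m`` fully compensating targets occupy indices 1..m (targets are
exchangeable, so this canonical ordering loses nothing).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationParams",
    "PopulationState",
    "FitnessScheme",
    "OutcomeSummary",
    "CloneSample",
    "validate_params",
    "build_fitness",
    "classify_outcome",
    "sample_clones",
    "class_labels",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameter set for one simulation run.

    Attributes
    ----------
    N : int
        Population size (census = effective).
    G : int
        Generations simulated after fixation of the resistant allele.
    mu : float
        Per-site, per-generation, per-cell mutation rate μ.  Every mutational
        target (the reversal site and each of the ``n`` compensatory sites)
        mutates at this rate.
    c : float
        Fitness cost of the resistance mutation in the original environment.
    p : float
        Proportion of the cost removed by an ordinary compensatory mutation.
    n : int
        Number of distinct compensatory mutational targets.
    m : int
        Number of those targets that are *fully* compensating (fitness 1).
    allow_second_mutation : bool
        Whether compensated cells may acquire a subsequent reversal mutation
        (COM -> CR).  Disabled for the pure reversion-vs-compensation race.
    presence_threshold : int
        Minimum copy number for a class to be called "present" at the end of
        a run (default 10 = 0.1% of the default N).
    sample_size : int
        Clones sampled per replicate for experiment-style output.
    seed : int
        RNG seed for the replicate.
    event_order : str
        ``"mutate_first"`` (default) applies mutation then fitness-weighted
        reproduction within each generation; ``"select_first"`` the reverse.
    """

    N: int = 10_000
    G: int = 100
    mu: float = 1e-5
    c: float = 0.15
    p: float = 0.5
    n: int = 100
    m: int = 0
    allow_second_mutation: bool = True
    presence_threshold: int = 10
    sample_size: int = 10
    seed: int = 0
    event_order: str = "mutate_first"

    # -- derived index layout -------------------------------------------------
    @property
    def n_classes(self) -> int:
        return self.n + 3

    @property
    def RES(self) -> int:
        return 0

    @property
    def WT(self) -> int:
        return self.n + 1

    @property
    def CR(self) -> int:
        return self.n + 2

    @property
    def com_slice(self) -> slice:
        """Slice covering all COM(i) classes (empty when n == 0)."""
        return slice(1, self.n + 1)

    @property
    def com_full_slice(self) -> slice:
        """Slice covering the fully compensating COM classes (indices 1..m)."""
        return slice(1, self.m + 1)

    @property
    def com_partial_slice(self) -> slice:
        return slice(self.m + 1, self.n + 1)

    @property
    def Nmu(self) -> float:
        """Mutation supply per target per generation."""
        return self.N * self.mu

    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)


def validate_params(params: SimulationParams) -> SimulationParams:
    """Check every invariant of :class:`SimulationParams`; return it unchanged.

    Raises ``ValueError`` on any violation.  The fully compensating set is
    canonical by construction (indices 1..m), so no rewriting is needed.
    """
    if params.N <= 0:
        raise ValueError(f"N must be positive, got {params.N}")
    if params.G <= 0:
        raise ValueError(f"G must be positive, got {params.G}")
    if not 0.0 <= params.mu <= 1.0:
        raise ValueError(f"mu must be a probability, got {params.mu}")
    if not 0.0 < params.c < 1.0:
        raise ValueError(f"c must lie in (0, 1), got {params.c}")
    if not 0.0 <= params.p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {params.p}")
    if params.n < 0:
        raise ValueError(f"n must be non-negative, got {params.n}")
    if not 0 <= params.m <= params.n:
        raise ValueError(f"m must satisfy 0 <= m <= n, got m={params.m}, n={params.n}")
    # a single cell faces n+1 mutational targets; total probability must be valid
    if params.mu * (params.n + 1) > 1.0:
        raise ValueError(
            f"total per-cell mutation probability mu*(n+1) = "
            f"{params.mu * (params.n + 1):g} exceeds 1"
        )
    if not 0 < params.presence_threshold <= params.N:
        raise ValueError("presence_threshold must lie in [1, N]")
    if not 0 < params.sample_size <= params.N:
        raise ValueError("sample_size must lie in [1, N]")
    if params.event_order not in ("mutate_first", "select_first"):
        raise ValueError(f"unknown event_order {params.event_order!r}")
    return params


def class_labels(params: SimulationParams) -> list[str]:
    """Human-readable label per class index: RES, COM(1)..COM(n), WT, CR."""
    return ["RES"] + [f"COM({i})" for i in range(1, params.n + 1)] + ["WT", "CR"]


def is_fully_compensating(params: SimulationParams, index: int) -> bool:
    """True iff class ``index`` is a fully compensating COM class."""
    return 1 <= index <= params.m


@dataclass(frozen=True)
class FitnessScheme:
    """Relative fitness per genotype class (vector of length n+3)."""

    w: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))


def build_fitness(params: SimulationParams) -> FitnessScheme:
    """Fitness vector: RES = 1-c, partial COM = 1-c(1-p), full COM/WT/CR = 1.

    Values come from the closed forms directly (no accumulation), so entries
    are exact to float precision.
    """
    w = np.ones(params.n_classes)
    w[params.RES] = 1.0 - params.c
    w[params.com_partial_slice] = 1.0 - params.c * (1.0 - params.p)
    # full COM classes, WT and CR stay at 1
    return FitnessScheme(w)


@dataclass(frozen=True)
class PopulationState:
    """Integer count per genotype class at one generation; sums to N."""

    generation: int
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "counts", np.asarray(self.counts, dtype=np.int64)
        )

    def check(self, params: SimulationParams) -> "PopulationState":
        if self.counts.shape != (params.n_classes,):
            raise ValueError(
                f"counts has shape {self.counts.shape}, expected ({params.n_classes},)"
            )
        if (self.counts < 0).any():
            raise ValueError("negative class count")
        if int(self.counts.sum()) != params.N:
            raise ValueError(
                f"counts sum to {int(self.counts.sum())}, expected N={params.N}"
            )
        return self


def initial_state(params: SimulationParams) -> PopulationState:
    """All-RES starting state: the maladapted population just after the sweep."""
    counts = np.zeros(params.n_classes, dtype=np.int64)
    counts[params.RES] = params.N
    return PopulationState(0, counts)


@dataclass(frozen=True)
class OutcomeSummary:
    """End-of-run presence flags and a derived categorical label.

    Presence of a class (or class group) means its final count reaches
    ``presence_threshold``; such a lineage is expected to fix eventually.
    ``two_background_reversal`` marks the soft-sweep signature: the reversal
    allele present both on its own (WT) and on a compensated background (CR).
    """

    wt_present: bool
    cr_present: bool
    any_com_present: bool
    res_present: bool
    two_background_reversal: bool
    label: str


def classify_outcome(
    final_state: PopulationState, params: SimulationParams
) -> OutcomeSummary:
    """Classify the final population state into an :class:`OutcomeSummary`.

    Label logic: ``soft_reversal`` if the reversal allele is present on both
    backgrounds; ``reversion`` if WT alone among the derived classes;
    ``compensation`` if only compensatory classes; ``persistence`` if only
    RES remains; ``mixed`` otherwise.
    """
    final_state.check(params)
    t = params.presence_threshold
    counts = final_state.counts
    wt = bool(counts[params.WT] >= t)
    cr = bool(counts[params.CR] >= t)
    com = bool(counts[params.com_slice].sum() >= t)
    res = bool(counts[params.RES] >= t)

    if wt and cr:
        label = "soft_reversal"
    elif wt and not cr and not com:
        label = "reversion"
    elif com and not wt and not cr:
        label = "compensation"
    elif res and not wt and not cr and not com:
        label = "persistence"
    else:
        label = "mixed"
    return OutcomeSummary(
        wt_present=wt,
        cr_present=cr,
        any_com_present=com,
        res_present=res,
        two_background_reversal=wt and cr,
        label=label,
    )


@dataclass(frozen=True)
class CloneSample:
    """Genotype labels of ``sample_size`` clones picked from one replicate."""

    replicate_id: int
    labels: list[str]
    class_counts: np.ndarray  # per-class sampled counts, length n+3


def sample_clones(
    final_state: PopulationState,
    params: SimulationParams,
    rng: np.random.Generator,
    replicate_id: int = 0,
) -> CloneSample:
    """Sample ``sample_size`` clones without replacement from the final state.

    This is the in-silico analogue of picking and sequencing colonies: a
    multivariate hypergeometric draw over the final class counts.
    """
    final_state.check(params)
    drawn = rng.multivariate_hypergeometric(
        final_state.counts, params.sample_size
    )
    names = class_labels(params)
    labels = [name for name, k in zip(names, drawn) for _ in range(int(k))]
    return CloneSample(replicate_id=replicate_id, labels=labels, class_counts=drawn)
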