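"""Exact Markov-chain enumeration for tiny populations.

For small N and few classes the Wright-Fisher chain has a manageable state
space (all compositions of N into n+3 parts), so the mutation and
reproduction kernels can be written as dense stochastic matrices, composed,
and powered.  The resulting exact outcome distribution is the independent
oracle against which the Monte-Carlo engine is validated; it is never used
for production runs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import multinomial as sp_multinomial

from .core import SimulationParams, build_fitness, validate_params

__all__ = ["ExactDistribution", "exact_small_oracle", "enumerate_states"]

DEFAULT_STATE_CAP = 100_000


def enumerate_states(N: int, k: int) -> np.ndarray:
    """All compositions of N into k non-negative parts, shape (S, k)."""
    states = [
        comp
        for comp in _compositions(N, k)
    ]
    return np.array(states, dtype=np.int64)


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def _n_states(N: int, k: int) -> int:
    return math.comb(N + k - 1, k - 1)


@dataclass(frozen=True)
class ExactDistribution:
    """Exact probability over final population states at generation G."""

    params: SimulationParams
    states: np.ndarray  # (S, n_classes)
    probs: np.ndarray  # (S,)

    def prob_count_at_least(self, class_index: int, threshold: int) -> float:
        """P(final count of one class >= threshold)."""
        mask = self.states[:, class_index] >= threshold
        return float(self.probs[mask].sum())

    def marginal_mean(self, class_index: int) -> float:
        return float((self.states[:, class_index] * self.probs).sum())


def _mutation_matrix(
    states: np.ndarray, index: dict, params: SimulationParams
) -> np.ndarray:
    """Dense transition matrix of the mutation kernel."""
    S = len(states)
    M = np.zeros((S, S))
    mu = params.mu
    n = params.n
    stay = 1.0 - (n + 1) * mu
    for si, state in enumerate(states):
        r = int(state[params.RES])
        com = state[params.com_slice].astype(int)
        # all ways to split r RES cells over [stay, COM(1..n), WT]
        for split in _compositions(r, n + 2):
            p_split = _multinomial_pmf(split, [stay] + [mu] * (n + 1))
            if p_split == 0.0:
                continue
            # conversions COM(i) -> CR from pre-mutation COM counts
            for conv in itertools.product(*(range(ci + 1) for ci in com)):
                p_conv = 1.0
                for ci, ji in zip(com, conv):
                    if params.allow_second_mutation:
                        p_conv *= _binom_pmf(ji, ci, mu)
                    elif ji > 0:
                        p_conv = 0.0
                        break
                if p_conv == 0.0:
                    continue
                new = state.copy()
                new[params.RES] = split[0]
                for i in range(n):
                    new[1 + i] += split[1 + i] - conv[i]
                new[params.WT] += split[n + 1]
                new[params.CR] += sum(conv)
                M[si, index[tuple(new)]] += p_split * p_conv
    return M


def _multinomial_pmf(counts, pvals) -> float:
    total = sum(counts)
    logp = math.lgamma(total + 1)
    for k, p in zip(counts, pvals):
        if k > 0:
            if p == 0.0:
                return 0.0
            logp += k * math.log(p) - math.lgamma(k + 1)
    return math.exp(logp)


def _binom_pmf(k: int, n: int, p: float) -> float:
    if k > n:
        return 0.0
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def _reproduction_matrix(
    states: np.ndarray, params: SimulationParams
) -> np.ndarray:
    """Dense transition matrix of fitness-weighted multinomial reproduction."""
    S = len(states)
    w = build_fitness(params).w
    R = np.empty((S, S))
    for si, state in enumerate(states):
        weights = state * w
        q = weights / weights.sum()
        R[si] = sp_multinomial.pmf(states, params.N, q)
    # guard tiny negative round-off from scipy's exp(logpmf)
    np.clip(R, 0.0, None, out=R)
    R /= R.sum(axis=1, keepdims=True)
    return R


def exact_small_oracle(
    params: SimulationParams, state_cap: int = DEFAULT_STATE_CAP
) -> ExactDistribution:
    """Exact final-state distribution by dense transition-matrix powering.

    Refuses state spaces larger than ``state_cap`` compositions.  Intended
    for validation on toy instances (e.g. N=10, n=1: 286 states).
    """
    validate_params(params)
    k = params.n_classes
    S = _n_states(params.N, k)
    if S > state_cap:
        raise ValueError(
            f"state space has {S} compositions, above the cap of {state_cap}"
        )
    states = enumerate_states(params.N, k)
    index = {tuple(s): i for i, s in enumerate(states)}
    M = _mutation_matrix(states, index, params)
    R = _reproduction_matrix(states, params)
    T = M @ R if params.event_order == "mutate_first" else R @ M
    v = np.zeros(S)
    start = np.zeros(k, dtype=np.int64)
    start[params.RES] = params.N
    v[index[tuple(start)]] = 1.0
    for _ in range(params.G):
        v = v @ T
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    return ExactDistribution(params=params, states=states, probs=v)
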