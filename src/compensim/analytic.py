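"""Deterministic trajectories and the reversal-vs-compensation race approximation.

The stochastic race of the simulator can be approximated by a hazard
integral.  The pooled compensatory class is treated deterministically
(mean-field): each generation it receives the mutational flux n*mu*x_RES
and is swept against the resistant residents until the residents drop
below the presence threshold (the deterministic stand-in for fixation).  While resistant cells remain, each
generation contributes a hazard of a *successful* wild-type reversal

    h_t = N * x_RES(t) * mu * P_fix(s_t, N),

where ``s_t = 1 / w_bar(t) - 1`` is the advantage of a wild-type cell over
the current mean fitness and ``P_fix`` is the Kimura diffusion fixation
probability.  The probability that at least one successful reversal occurs
before the compensatory class fixes is ``1 - exp(-sum_t h_t)``.

This approximation assumes the reversal is the only mutation rising when it
occurs; under high mutation supply many lineages sweep simultaneously and
the approximation overestimates the reversal probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SimulationParams, validate_params

__all__ = [
    "RaceApproximationResult",
    "deterministic_sweep",
    "fixation_probability",
    "p_reversal_before_fixation",
    "expected_reversal_share",
    "race_curve",
]


def deterministic_sweep(
    w_invader: float, w_resident: float, x0: float, G: int
) -> np.ndarray:
    """Deterministic haploid selection: iterate the invader frequency G times.

    x' = x w_i / (x w_i + (1-x) w_r).  Returns the length-(G+1) trajectory.
    """
    if not 0.0 < x0 < 1.0:
        raise ValueError(f"x0 must be interior, got {x0}")
    if w_invader <= 0 or w_resident <= 0:
        raise ValueError("fitnesses must be positive")
    traj = np.empty(G + 1)
    x = x0
    traj[0] = x
    for t in range(1, G + 1):
        x = x * w_invader / (x * w_invader + (1.0 - x) * w_resident)
        traj[t] = x
    return traj


def fixation_probability(s: float, N: int) -> float:
    """Kimura diffusion fixation probability of a single new mutant.

    (1 - exp(-2s)) / (1 - exp(-2Ns)), continuous at s = 0 where it equals
    1/N.  For the deleterious side it decays smoothly, so the formula is
    usable over the whole selection range.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if abs(s) < 1e-12:
        return 1.0 / N
    num = -np.expm1(-2.0 * s)
    den = -np.expm1(-2.0 * N * s)
    return float(num / den)


@dataclass(frozen=True)
class RaceApproximationResult:
    """Output of the race approximation for one parameter set."""

    p_wt_wins: float
    t_fix_com: int
    per_generation_hazard: np.ndarray


def p_reversal_before_fixation(params: SimulationParams) -> RaceApproximationResult:
    """Probability that a successful WT reversal occurs before compensation fixes.

    Mirrors the race the simulator runs with second mutations disabled and
    no fully compensating targets (m = 0): either a reversal establishes
    while resistant cells remain, or the compensatory class fixes.
    """
    validate_params(params)
    N, mu, G = params.N, params.mu, params.G
    w_res = 1.0 - params.c
    w_com = 1.0 - params.c * (1.0 - params.p)

    if mu == 0.0:
        return RaceApproximationResult(0.0, G, np.zeros(G))

    if params.n == 0 or w_com == w_res:
        # no (effective) compensatory competitor: resistant residents persist
        x_res = np.ones(G)
        t_fix = G
    else:
        # mean-field compensatory dynamics: the pooled COM class receives the
        # full mutational flux n*mu*x_RES each generation and is then swept
        # deterministically against the resistant residents
        x_res_full = np.empty(G + 1)
        xr, xc = 1.0, 0.0
        x_res_full[0] = xr
        for t in range(1, G + 1):
            flux = xr * params.n * mu
            xr -= flux
            xc += flux
            wbar = xr * w_res + xc * w_com
            xr, xc = xr * w_res / wbar, xc * w_com / wbar
            x_res_full[t] = xr
        below = np.nonzero(x_res_full < params.presence_threshold / N)[0]
        t_fix = int(below[0]) if below.size else G
        x_res = x_res_full[:t_fix]

    w_bar = x_res * w_res + (1.0 - x_res) * w_com
    hazards = np.array(
        [
            N * xr * mu * fixation_probability(1.0 / wb - 1.0, N)
            for xr, wb in zip(x_res, w_bar)
        ]
    )
    p = float(-np.expm1(-hazards.sum()))
    return RaceApproximationResult(
        p_wt_wins=p, t_fix_com=t_fix, per_generation_hazard=hazards
    )


def expected_reversal_share(m: int) -> float:
    """Long-run expected population share of the reversal lineage.

    When m fully compensating lineages (fitness 1, each arising at the same
    rate mu as the reversal) race the reversal under abundant mutation
    supply, the m+1 equal competitors split the population evenly, leaving
    the reversal lineage with 1/(m+1).
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    return 1.0 / (m + 1)


def race_curve(
    base_params: SimulationParams, mus: "np.ndarray | list[float]"
) -> pd.DataFrame:
    """Analytic (Nmu, p_wt_wins) table over a mutation-rate grid."""
    rows = []
    for mu in mus:
        p = base_params.replace(mu=float(mu))
        res = p_reversal_before_fixation(p)
        rows.append(
            {
                "mu": float(mu),
                "Nmu": p.Nmu,
                "p_wt_wins": res.p_wt_wins,
                "t_fix_com": res.t_fix_com,
            }
        )
    return pd.DataFrame(rows)
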