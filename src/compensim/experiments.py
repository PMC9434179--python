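"""Replicate grids, outcome tables and summary statistics.

These functions reproduce the package's four standard computational
experiments at configurable replicate counts:

* the reversion-vs-compensation race (second mutations disabled, 500
  generations) with the analytic approximation overplotted;
* two-background (soft) reversal detection (second mutations allowed, 100
  generations);
* experiment-scale panels: a handful of populations with a handful of
  sequenced clones each;
* the effect of m fully compensating mutations on the number of reverted
  clones in a sample, across mutation-supply regimes.

Every grid is reproducible from its master seed: one child SeedSequence is
spawned per parameter cell, in cell order, and all replicates of a cell run
as one vectorized batch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analytic import race_curve
from .core import SimulationParams, validate_params
from .simulate import run_batch

__all__ = [
    "ExperimentGrid",
    "run_grid",
    "summarize",
    "realize_supply",
    "run_reversion_race_experiment",
    "run_soft_reversal_experiment",
    "run_clone_panel_experiment",
    "run_full_compensation_experiment",
]

#: parameter columns echoed into every outcome-table row
PARAM_COLS = ["N", "G", "mu", "c", "p", "n", "m", "allow_second_mutation", "Nmu"]


@dataclass(frozen=True)
class ExperimentGrid:
    """A cartesian sweep over simulation parameters.

    ``swept`` maps parameter names (any of mu, p, n, m, c, G, N) to value
    lists; the run set is the cartesian product of the swept values times
    ``replicates``.
    """

    base_params: SimulationParams
    swept: Mapping[str, Sequence] = field(default_factory=dict)
    replicates: int = 1000
    master_seed: int = 0

    def cells(self) -> list[SimulationParams]:
        keys = list(self.swept)
        out = []
        for values in itertools.product(*(self.swept[k] for k in keys)):
            out.append(self.base_params.replace(**dict(zip(keys, values))))
        return out


def realize_supply(
    Nmu: float, base_N: int = 10_000, mu_cap: float = 1e-3
) -> tuple[int, float]:
    """Realize a target mutation supply Nmu as a valid (N, mu) pair.

    mu = Nmu / base_N where that stays at or below ``mu_cap``; larger
    supplies keep mu at the cap and scale the population up instead, since
    supply (the product) is the composite that controls the dynamics and
    per-cell mutation probabilities must remain valid.
    """
    mu = Nmu / base_N
    if mu <= mu_cap:
        return base_N, mu
    return int(round(Nmu / mu_cap)), mu_cap


def _run_cell(
    params: SimulationParams,
    replicates: int,
    seed_seq: np.random.SeedSequence,
    collect_samples: bool,
) -> pd.DataFrame:
    """Run one grid cell and tabulate per-replicate outcomes."""
    validate_params(params)
    rng = np.random.default_rng(seed_seq)
    finals = run_batch(params, replicates, rng)

    thr = params.presence_threshold
    wt = finals[:, params.WT]
    cr = finals[:, params.CR]
    res = finals[:, params.RES]
    com_full = finals[:, params.com_full_slice].sum(axis=1)
    com_partial = finals[:, params.com_partial_slice].sum(axis=1)
    com_any = com_full + com_partial

    wt_p = wt >= thr
    cr_p = cr >= thr
    com_p = com_any >= thr
    res_p = res >= thr
    label = np.where(
        wt_p & cr_p,
        "soft_reversal",
        np.where(
            wt_p & ~com_p,
            "reversion",
            np.where(
                com_p & ~wt_p & ~cr_p,
                "compensation",
                np.where(res_p & ~wt_p & ~cr_p & ~com_p, "persistence", "mixed"),
            ),
        ),
    )

    table = pd.DataFrame(
        {
            "replicate": np.arange(replicates),
            "wt_present": wt_p,
            "cr_present": cr_p,
            "any_com_present": com_p,
            "res_present": res_p,
            "two_background_reversal": wt_p & cr_p,
            "label": label,
            "count_res": res,
            "count_com_partial": com_partial,
            "count_com_full": com_full,
            "count_wt": wt,
            "count_cr": cr,
            "share_wt": wt / params.N,
            "share_reversal_allele": (wt + cr) / params.N,
            "share_com_full_lineage": (com_full + cr) / params.N,
        }
    )
    for col in PARAM_COLS:
        table.insert(0, col, getattr(params, col))

    if collect_samples:
        k = params.sample_size
        s_res = np.empty(replicates, dtype=np.int64)
        s_full = np.empty_like(s_res)
        s_partial = np.empty_like(s_res)
        s_wt = np.empty_like(s_res)
        s_cr = np.empty_like(s_res)
        for i in range(replicates):
            drawn = rng.multivariate_hypergeometric(finals[i], k)
            s_res[i] = drawn[params.RES]
            s_full[i] = drawn[params.com_full_slice].sum()
            s_partial[i] = drawn[params.com_partial_slice].sum()
            s_wt[i] = drawn[params.WT]
            s_cr[i] = drawn[params.CR]
        table["sampled_res"] = s_res
        table["sampled_com_full"] = s_full
        table["sampled_com_partial"] = s_partial
        table["sampled_wt"] = s_wt
        table["sampled_cr"] = s_cr
        table["reverted_clones_wt_only"] = s_wt
        table["reverted_clones_any"] = s_wt + s_cr
    return table


def run_grid(grid: ExperimentGrid, collect_samples: bool = False) -> pd.DataFrame:
    """Run every cell of the grid; one row per (cell, replicate)."""
    cells = grid.cells()
    seeds = np.random.SeedSequence(grid.master_seed).spawn(len(cells))
    frames = [
        _run_cell(p, grid.replicates, s, collect_samples)
        for p, s in zip(cells, seeds)
    ]
    return pd.concat(frames, ignore_index=True)


def summarize(table: pd.DataFrame, by: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-cell outcome probabilities with binomial SEs and count percentiles.

    Presence flags are averaged into probabilities with SE sqrt(p(1-p)/R);
    sampled-clone and share columns get means plus 2.5/97.5 percentiles of
    the replicate distribution.
    """
    if table.empty:
        raise ValueError("empty outcome table")
    if by is None:
        by = [c for c in PARAM_COLS if c in table.columns]
    flag_cols = [
        c
        for c in (
            "wt_present",
            "cr_present",
            "any_com_present",
            "res_present",
            "two_background_reversal",
        )
        if c in table.columns
    ]
    stat_cols = [
        c
        for c in table.columns
        if c.startswith(("sampled_", "reverted_clones", "share_"))
    ]

    rows = []
    for key, group in table.groupby(list(by), sort=False):
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        R = len(group)
        rec["replicates"] = R
        for c in flag_cols:
            phat = group[c].mean()
            rec[f"P_{c}"] = phat
            rec[f"SE_{c}"] = float(np.sqrt(phat * (1 - phat) / R))
        for c in stat_cols:
            rec[f"mean_{c}"] = group[c].mean()
            rec[f"q2.5_{c}"] = group[c].quantile(0.025)
            rec[f"q97.5_{c}"] = group[c].quantile(0.975)
        rows.append(rec)
    return pd.DataFrame(rows)


def run_reversion_race_experiment(grid: ExperimentGrid) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The reversion-vs-compensation race with the analytic lines joined.

    Forces the race setting: no second mutations, no fully compensating
    targets, 500 generations.  Returns (outcome table, per-cell summary with
    the analytic reversal probability for cells swept over mu).
    """
    base = grid.base_params.replace(
        allow_second_mutation=False, m=0, G=500
    )
    grid = ExperimentGrid(base, grid.swept, grid.replicates, grid.master_seed)
    table = run_grid(grid)
    summary = summarize(table)
    analytic_rows = []
    for cell in grid.cells():
        from .analytic import p_reversal_before_fixation

        analytic_rows.append(
            {
                **{c: getattr(cell, c) for c in ("mu", "p", "n", "c", "N", "G")},
                "p_wt_wins_analytic": p_reversal_before_fixation(cell).p_wt_wins,
            }
        )
    summary = summary.merge(
        pd.DataFrame(analytic_rows), on=["mu", "p", "n", "c", "N", "G"], how="left"
    )
    return table, summary


def run_soft_reversal_experiment(grid: ExperimentGrid) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-background (soft) reversal probability across the grid.

    Forces second mutations on, m = 0, 100 generations; the statistic is
    P(WT present AND CR present) under the presence threshold.
    """
    base = grid.base_params.replace(allow_second_mutation=True, m=0, G=100)
    grid = ExperimentGrid(base, grid.swept, grid.replicates, grid.master_seed)
    table = run_grid(grid)
    return table, summarize(table)


def run_clone_panel_experiment(
    params_per_panel: Sequence[SimulationParams],
    populations: int = 10,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Experiment-scale panels: a few populations, a few sequenced clones each.

    Returns a tidy table with one row per sampled clone: (panel Nmu,
    population, clone index, genotype group label).
    """
    from .core import class_labels

    seeds = np.random.SeedSequence(master_seed).spawn(len(params_per_panel))
    rows = []
    for params, seed_seq in zip(params_per_panel, seeds):
        validate_params(params)
        rng = np.random.default_rng(seed_seq)
        finals = run_batch(params, populations, rng)
        names = class_labels(params)
        for pop in range(populations):
            drawn = rng.multivariate_hypergeometric(
                finals[pop], params.sample_size
            )
            clone = 0
            for idx, k in enumerate(drawn):
                for _ in range(int(k)):
                    rows.append(
                        {
                            "Nmu": params.Nmu,
                            "mu": params.mu,
                            "N": params.N,
                            "population": pop,
                            "clone": clone,
                            "label": names[idx],
                        }
                    )
                    clone += 1
    return pd.DataFrame(rows)


def run_full_compensation_experiment(
    supplies: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    m_values: Sequence[int] = (0, 1, 3, 5, 10),
    base_params: SimulationParams | None = None,
    replicates: int = 1000,
    master_seed: int = 0,
    count_cr_as_reverted: bool = False,
    allow_second_mutation: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reverted clones per sample under m fully compensating mutations.

    Sweeps mutation supply x m; each supply is realized via
    :func:`realize_supply`; runs last 100 generations.  By default second
    mutations are disabled so the experiment is a pure race between the
    reversal lineage and the m fully compensating lineages — the setting in
    which the m+1 equal-fitness, equal-rate competitors partition the
    population as 1/(m+1) each (with one fully compensating mutation, half
    the population ends compensated and half wild type; with three, 2.5
    reverted clones are expected in a sample of 10).  Allowing second
    mutations adds compensated-reversal lineages that absorb a large share
    of the population at high supply and breaks that clean partition.

    The per-replicate statistic is the number of sampled clones carrying
    the reversal allele — by default only clones without a compensatory
    mutation (WT) count; set ``count_cr_as_reverted`` to also count
    compensated reversals.
    """
    if base_params is None:
        base_params = SimulationParams()
    cells = []
    for m in m_values:
        for s in supplies:
            N, mu = realize_supply(s, base_params.N)
            cells.append(
                base_params.replace(
                    N=N,
                    mu=mu,
                    m=m,
                    G=100,
                    allow_second_mutation=allow_second_mutation,
                )
            )
    seeds = np.random.SeedSequence(master_seed).spawn(len(cells))
    frames = [
        _run_cell(p, replicates, s, collect_samples=True)
        for p, s in zip(cells, seeds)
    ]
    table = pd.concat(frames, ignore_index=True)
    table["reverted_clones"] = (
        table["reverted_clones_any"]
        if count_cr_as_reverted
        else table["reverted_clones_wt_only"]
    )
    summary = summarize(table)
    return table, summary
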