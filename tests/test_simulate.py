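"""Mutation kernel, selection-drift kernel, replicate runner and batch runner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compensim import (
    FitnessScheme,
    PopulationState,
    SimulationParams,
    build_fitness,
    initial_state,
    mutate_step,
    replicate_rng,
    run_batch,
    run_replicate,
    selection_drift_step,
)


def make_state(params, counts):
    return PopulationState(0, np.asarray(counts, dtype=np.int64))


class TestMutateStep:
    def test_zero_rate_is_identity(self, rng):
        p = SimulationParams(mu=0.0, n=3)
        s = make_state(p, [4000, 1000, 2000, 500, 2000, 500])
        out = mutate_step(s, p, rng)
        assert np.array_equal(out.counts, s.counts)

    def test_expected_mutant_influx(self, rng):
        # RES=10,000, mu=1e-3, n=100: E[new WT] = N*mu = 10,
        # E[new COM total] = N*n*mu = 1,000 per generation
        p = SimulationParams(N=10_000, mu=1e-3, n=100, m=0)
        s = initial_state(p)
        reps = 10_000
        wt = np.empty(reps)
        com = np.empty(reps)
        for i in range(reps):
            out = mutate_step(s, p, rng)
            wt[i] = out.counts[p.WT]
            com[i] = out.counts[p.com_slice].sum()
        for draws, mean in ((wt, 10.0), (com, 1000.0)):
            se = draws.std(ddof=1) / np.sqrt(reps)
            assert abs(draws.mean() - mean) < 3 * se

    def test_no_second_mutation_when_disabled(self, rng):
        p = SimulationParams(mu=1e-2, n=5, allow_second_mutation=False)
        s = make_state(p, [0, 0, 0, 0, 0, 10_000, 0, 0])  # all COM(5)
        for _ in range(50):
            out = mutate_step(s, p, rng)
            assert out.counts[p.CR] == 0

    def test_com_to_cr_flux_when_enabled(self, rng):
        p = SimulationParams(N=10_000, mu=1e-3, n=1, m=0)
        s = make_state(p, [0, 10_000, 0, 0])
        draws = np.array(
            [mutate_step(s, p, rng).counts[p.CR] for _ in range(5000)]
        )
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 10.0) < 3 * se

    def test_mutation_never_refills_res_or_drains_wt(self, rng):
        p = SimulationParams(mu=1e-2, n=2)
        s = make_state(p, [5000, 1000, 1000, 2000, 1000])
        for _ in range(100):
            out = mutate_step(s, p, rng)
            assert out.counts[p.RES] <= s.counts[p.RES]
            assert out.counts[p.WT] >= s.counts[p.WT]
            assert out.counts[p.CR] >= s.counts[p.CR]
            assert out.counts.sum() == p.N


class TestSelectionDriftStep:
    def test_monomorphic_is_fixed_point(self, rng):
        p = SimulationParams(n=2)
        fit = build_fitness(p)
        s = make_state(p, [0, 0, p.N, 0, 0])
        out = selection_drift_step(s, fit, p, rng)
        assert np.array_equal(out.counts, s.counts)
        assert out.generation == 1

    def test_neutral_drift_variance(self, rng):
        # equal-fitness split 5000/5000: next-generation frequency has
        # mean 0.5 and variance x(1-x)/N = 0.25/N
        p = SimulationParams(N=10_000, n=1)
        fit = FitnessScheme(np.ones(p.n_classes))  # strict neutrality
        s = make_state(p, [5000, 0, 5000, 0])
        freqs = np.array(
            [
                selection_drift_step(s, fit, p, rng).counts[p.WT] / p.N
                for _ in range(10_000)
            ]
        )
        se = freqs.std(ddof=1) / np.sqrt(10_000)
        assert abs(freqs.mean() - 0.5) < 4 * se
        target_var = 0.25 / p.N
        # variance of the sample variance ~ 2 var^2 / n for near-binomial draws
        assert abs(freqs.var(ddof=1) - target_var) < 4 * target_var * np.sqrt(
            2 / 10_000
        )

    def test_selection_shifts_expected_frequency(self, rng):
        # WT=100 vs RES=9,900 at c=0.15: E[next WT freq] = 100/(100+9900*0.85)
        p = SimulationParams(N=10_000, n=0, c=0.15)
        fit = build_fitness(p)
        s = make_state(p, [9900, 100, 0])
        expected = 100.0 / (100.0 + 9900.0 * 0.85)
        assert abs(expected - 0.011744) < 1e-6
        freqs = np.array(
            [
                selection_drift_step(s, fit, p, rng).counts[p.WT] / p.N
                for _ in range(10_000)
            ]
        )
        se = freqs.std(ddof=1) / 100
        assert abs(freqs.mean() - expected) < 3 * se


class TestRunReplicate:
    def test_mu_zero_stays_all_res(self):
        p = SimulationParams(N=500, G=50, mu=0.0, n=2)
        traj = run_replicate(p)
        assert traj.final.counts[p.RES] == p.N
        assert len(traj.states) == p.G + 1

    def test_seed_determinism(self):
        p = SimulationParams(N=1000, G=30, mu=1e-3, n=3, seed=42)
        a = run_replicate(p)
        b = run_replicate(p)
        assert np.array_equal(a.counts_matrix(), b.counts_matrix())

    def test_replicate_rng_streams_are_distinct(self):
        p = SimulationParams(N=1000, G=30, mu=1e-3, n=3)
        a = run_replicate(p, replicate_rng(7, 0))
        b = run_replicate(p, replicate_rng(7, 1))
        assert not np.array_equal(a.counts_matrix(), b.counts_matrix())

    def test_counts_conserved_every_generation(self):
        p = SimulationParams(N=2000, G=60, mu=1e-3, n=4, seed=3)
        traj = run_replicate(p)
        sums = traj.counts_matrix().sum(axis=1)
        assert np.all(sums == p.N)

    def test_cr_unreachable_when_second_mutation_disabled(self):
        p = SimulationParams(
            N=2000, G=100, mu=1e-3, n=4, allow_second_mutation=False, seed=5
        )
        traj = run_replicate(p)
        assert np.all(traj.counts_matrix()[:, p.CR] == 0)

    def test_event_order_switch_runs(self):
        p = SimulationParams(N=500, G=20, mu=1e-3, n=2, event_order="select_first")
        traj = run_replicate(p)
        assert traj.final.counts.sum() == p.N

    @given(
        N=st.integers(min_value=2, max_value=50),
        n=st.integers(min_value=0, max_value=3),
        mu=st.floats(min_value=0.0, max_value=0.2),
        allow=st.booleans(),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_trajectory_invariants_property(self, N, n, mu, allow, seed):
        p = SimulationParams(
            N=N,
            G=10,
            mu=mu,
            n=n,
            m=0,
            allow_second_mutation=allow,
            presence_threshold=1,
            sample_size=1,
            seed=seed,
        )
        traj = run_replicate(p)
        counts = traj.counts_matrix()
        assert np.all(counts.sum(axis=1) == N)
        assert np.all(counts >= 0)
        if not allow:
            assert np.all(counts[:, p.CR] == 0)


class TestRunBatch:
    def test_batch_shape_and_conservation(self, rng):
        p = SimulationParams(N=500, G=20, mu=1e-3, n=3)
        finals = run_batch(p, 50, rng)
        assert finals.shape == (50, p.n_classes)
        assert np.all(finals.sum(axis=1) == p.N)

    def test_batch_reproducible_from_seed(self):
        p = SimulationParams(N=500, G=20, mu=1e-3, n=3)
        a = run_batch(p, 40, np.random.default_rng(9))
        b = run_batch(p, 40, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_batch_matches_single_replicate_distribution(self):
        # same physics on both paths: mean final WT frequency must agree
        p = SimulationParams(N=200, G=30, mu=5e-3, n=1, presence_threshold=1)
        finals = run_batch(p, 2000, np.random.default_rng(10))
        singles = np.array(
            [
                run_replicate(p, replicate_rng(11, i)).final.counts[p.WT]
                for i in range(400)
            ]
        )
        pooled_se = np.sqrt(
            finals[:, p.WT].var(ddof=1) / 2000 + singles.var(ddof=1) / 400
        )
        assert abs(finals[:, p.WT].mean() - singles.mean()) < 4 * pooled_se
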