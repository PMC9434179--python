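"""The race between reversion and compensation across mutation supplies.

With second mutations disabled there are only two long-term outcomes: either
a wild-type reversal establishes while resistant cells remain, or the
compensatory mutations fix first.  Simulated probabilities (200 replicates
per supply, 500 generations) are compared with the analytic hazard-integral
approximation.
"""

from compensim import ExperimentGrid, SimulationParams, run_reversion_race_experiment

base = SimulationParams(N=10_000)
supplies = [0.001, 0.01, 0.1, 1.0, 10.0]
grid = ExperimentGrid(
    base, {"mu": [s / base.N for s in supplies]}, replicates=200, master_seed=0
)
table, summary = run_reversion_race_experiment(grid)

print("Nmu      P(reversal) +/- SE    analytic")
for _, row in summary.iterrows():
    print(
        f"{row['Nmu']:<8g} {row['P_wt_present']:.3f} +/- {row['SE_wt_present']:.3f}"
        f"       {row['p_wt_wins_analytic']:.3f}"
    )
print(
    "\nReversal wins rarely when mutations are scarce (Nmu <= 0.01) and "
    "almost surely when supply is high (Nmu >= 1); the analytic line "
    "overestimates slightly once several lineages sweep at once."
)
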