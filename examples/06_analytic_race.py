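"""The hazard-integral approximation of the reversion-vs-compensation race.

The pooled compensatory class is swept deterministically (fed by its
mutational flux); each generation while resistant cells remain contributes
a hazard N * x_RES * mu * P_fix of a successful reversal.  The probability
that reversal wins is 1 - exp(-total hazard).
"""

from compensim import (
    SimulationParams,
    fixation_probability,
    p_reversal_before_fixation,
    race_curve,
)

base = SimulationParams(N=10_000, G=500, allow_second_mutation=False, m=0)

print("Kimura fixation probability of a new beneficial mutation:")
for s in (0.0, 0.075, 0.15):
    print(f"  s = {s:<6}: P_fix = {fixation_probability(s, base.N):.4f}")

res = p_reversal_before_fixation(base.replace(mu=1e-5))
print(
    f"\nAt Nmu = 0.1: compensation needs {res.t_fix_com} generations to fix;"
    f" P(reversal first) = {res.p_wt_wins:.3f}"
)

curve = race_curve(base, [s / base.N for s in (0.001, 0.01, 0.1, 1.0, 10.0)])
print("\nNmu vs analytic reversal probability:")
print(curve[["Nmu", "p_wt_wins", "t_fix_com"]].to_string(index=False))
print(
    "\nHigher supply shortens the wait for a successful reversal faster "
    "than it speeds up compensatory fixation, so reversal dominates at "
    "high Nmu."
)
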