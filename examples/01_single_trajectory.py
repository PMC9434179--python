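"""Run one replicate and watch the post-sweep dynamics.

A population of 10,000 resistant bacteria evolves for 100 generations at an
intermediate mutation supply (Nmu = 0.1).  Typically several compensatory
lineages rise first and a wild-type reversal then outcompetes them.
"""

from compensim import SimulationParams, classify_outcome, run_replicate
from compensim.io import trajectory_to_frame

params = SimulationParams(N=10_000, G=100, mu=1e-5, seed=4)
traj = run_replicate(params)

frame = trajectory_to_frame(traj)
final = frame[frame["generation"] == params.G]
print("final nonzero classes:")
print(final[["class_label", "count"]].to_string(index=False))

outcome = classify_outcome(traj.final, params)
print(f"\noutcome label: {outcome.label}")
print(
    "flags: WT present =", outcome.wt_present,
    "| any compensation =", outcome.any_com_present,
    "| resistant remains =", outcome.res_present,
)
print(
    "\nA class counts as 'present' with >= "
    f"{params.presence_threshold} copies (0.1% of N); a present fitter "
    "lineage is expected to fix eventually."
)
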