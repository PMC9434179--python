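# Methods

## Model

`compensim` follows a haploid, asexual population of fixed size `N` in
discrete, non-overlapping generations (Wright–Fisher). The starting
population is monomorphic for a resistance allele that has just fixed and,
with the selective pressure gone, carries cost `c` (fitness `1 − c`
relative to wild type). Genotypes are tracked as `n + 3` classes:

| class | origin | fitness |
|---|---|---|
| RES | starting genotype | `1 − c` |
| COM(i), i = 1…n | RES + i-th compensatory mutation | `1 − c(1−p)`, or `1` if `i ≤ m` |
| WT | RES + reversal mutation | `1` |
| CR | COM(i) + reversal mutation | `1` |

Each generation applies two kernels, by default mutation first (the order
is switchable via `event_order`; at `μ ≤ 1e−3` and `s ≤ 0.15` the two
orders differ per generation by `O(μs)` and do not move regime
boundaries):

1. **Mutation.** Every mutational target mutates at the same per-cell,
   per-generation rate `μ`. A RES cell moves to WT or to one of the `n`
   COM classes — a single multinomial draw over the RES count with
   per-destination probability `μ` and stay probability `1 − (n+1)μ`
   (exchangeability of cells within a class makes this exactly equivalent
   to per-cell Bernoulli draws). If second mutations are enabled, each COM
   class loses `Binomial(count, μ)` cells to CR. At most one mutational
   step per cell per generation: COM cells created in a generation cannot
   convert to CR in the same generation, a RES cell cannot reach CR in one
   step, and double-hit probabilities (`≤ μ² = 1e−6`) are neglected.
   WT and CR never mutate further; COM(i)→COM(j) and back-mutation to RES
   are not modelled (one compensatory mutation per cell; resistance is
   never re-selected).
2. **Reproduction.** The next generation is one multinomial draw of size
   `N` with class probabilities proportional to `count × fitness` —
   selection and drift in a single step. Counts are integers throughout;
   no frequency-space shortcuts, so drift variance is exact even for
   classes near the presence threshold.

Validation rejects `(n+1)μ > 1` (the per-cell mutation probabilities must
form a valid distribution), `m > n`, and non-positive `N`, `G`.

## Parameter defaults

| symbol | default | meaning |
|---|---|---|
| `N` | 10,000 | census = effective population size |
| `G` | 100 (500 for the race experiment) | generations after fixation of the resistant allele |
| `μ` | grid `1e−7 … 1e−3` (supply `Nμ` = 0.001 … 10) | per-site, per-generation mutation rate |
| `c` | 0.15 (0.05 and 0.3 supported) | cost of resistance |
| `p` | 0.5 | fraction of the cost removed by an ordinary compensatory mutation |
| `n` | 100 | number of compensatory targets |
| `m` | 0 (panels use 1, 3, 5, 10) | fully compensating targets, canonically indices 1…m |
| presence threshold | 10 individuals (0.1% of N) | a class this common is called present and expected to fix |
| sample size | 10 clones per replicate | experiment-scale sequencing analogue |

At `c = 0.15`, `p = 0.5` the relative fitnesses are 0.85 (resistant),
0.925 (partially compensated) and 1.0 (wild type, fully compensated, CR).

Mutation supplies above `Nμ = 10` cannot be realized at `N = 10,000`
without `(n+1)μ` exceeding 1; `realize_supply` therefore caps `μ` at
`1e−3` and scales `N` up instead (e.g. `Nμ = 100` → `N = 100,000`,
`μ = 1e−3`). Supply, not the rate alone, is the composite that controls
the dynamics.

## Outcome classification and clone sampling

Presence flags compare final class counts (COM classes pooled) to the
threshold; `two_background_reversal` = WT present AND CR present is the
soft-sweep signature. The five-way label {persistence, compensation,
reversion, soft_reversal, mixed} is derived sugar over the flags, which
are the primitive truth. Clone samples are multivariate hypergeometric
draws (without replacement — colony picking); with replacement would
differ by `O(k/N) = 0.001` and is not offered.

## The full-compensation experiment and the 1/(m+1) partition

With abundant supply, the reversal lineage and the `m` fully compensating
lineages are `m+1` exchangeable competitors (equal fitness 1, equal
mutation rate `μ` out of RES), so each is expected to end at share
`1/(m+1)`. The experiment runner (`run_full_compensation_experiment`) therefore
defaults to the pure race — second mutations disabled — in which this
partition is realized cleanly. With second mutations enabled,
compensated-reversal lineages seeded from the (large, transient)
partially compensated background act as extra fitness-1 competitors and
absorb a substantial share at high supply, breaking the clean partition;
that variant remains available via `allow_second_mutation=True`, and
whether CR clones count as "reverted" in samples is a separate switch
(`count_cr_as_reverted`, default off: a reverted clone is one carrying
the reversal allele and no compensatory mutation).

Two small systematic effects at `G = 100` are worth knowing: the sweep of
the fitness-1 lineages is ~97–99% complete, leaving a 1–6% residue of
partially compensated cells (larger for small `m`, since fewer fitness-1
lineages are seeded per generation), so measured shares sit slightly
below `1/(m+1)`; and the equal split between the reversal and the fully
compensating lineages is exact only conditionally on the swept mass,
which is how the test suite checks it.

## The analytic race approximation

For the race setting (second mutations off, `m = 0`) the probability that
a wild-type reversal establishes before compensation fixes is
approximated by:

1. **Mean-field compensatory sweep.** The pooled COM class is
   deterministic: each generation it receives the mutational flux
   `n·μ·x_RES` and is then swept against RES
   (`x' = x·w / w̄`). This is the deterministic limit of the
   mutation–selection dynamics and needs no ad-hoc seeding. "Fixation" is
   the first generation `t_fix` at which the RES frequency falls below
   the presence threshold `10/N` (literal absorption never happens
   deterministically).
2. **Reversal hazard.** While resistant cells remain (`t < t_fix`), each
   generation contributes hazard `h_t = N·x_RES(t)·μ·P_fix(s_t, N)`,
   where `s_t = 1/w̄_t − 1` is the advantage of a wild-type cell over the
   current mean fitness and `P_fix` is the Kimura diffusion form
   `(1 − e^{−2s})/(1 − e^{−2Ns})` (continuous at `s → 0` with limit
   `1/N`; preferred over `2s` for sanity at small `s` and small `N` — at
   these parameters the two differ by <10%).
3. `P(reversal first) = 1 − exp(−Σ_t h_t)`.

The approximation assumes the reversal is the only mutation rising when
it occurs and that its fate is set by the selection coefficient in its
generation of origin. Under high supply many lineages sweep
simultaneously, mean fitness rises faster than assumed, and the
approximation overestimates — the documented bias direction. At
`Nμ ≤ 0.1` it tracks simulation within a few percentage points; at
`Nμ ≥ 1` both are ≈1.

## Verification strategy

* **Exact oracle.** On toy instances (e.g. `N = 10`, `n = 1`: 286
  states) the mutation and reproduction kernels are written as dense
  stochastic matrices over all compositions of `N`, composed and powered
  `G` times. The Monte-Carlo engine must reproduce the exact
  `P(WT ≥ 1)` within Monte-Carlo error (50,000 replicates, 3 SE). This
  is the primary correctness test of the engine.
* **Closed forms.** Fitness entries, the neutral drift variance
  `x(1−x)/N`, expected mutant influx `Nμ` / `Nnμ`, deterministic sweep
  iterations and the Kimura formula are asserted against hand-evaluated
  values.
* **Regime structure.** Monotone reversal probability in `Nμ`, the sharp
  two-background transition between `Nμ = 0.1` and 1, clone-panel
  composition shifts, and the `1/(m+1)` law (regression slope within
  [0.85, 1.15] across `m ∈ {0,1,3,5,10}`).

Stochastic tests run at desk scale — 200–400 replicates per cell rather
than 1,000 — with Monte-Carlo-aware tolerances (binomial SEs, Wilson
bounds for saturated proportions); seeds are fixed. Default replicate
count for production grids remains 1,000.

## What the simulations do and do not emulate

The generator reproduces the study conditions — fixed `N`, constant
environment after one shift, a single-mutation resistance locus, equal
mutation rates across targets, and a smooth (epistasis-free) fitness
landscape. Real populations have unknown and time-varying effective
sizes, more complex demography (e.g. serial dilution), horizontal gene
transfer, sign epistasis and multi-step reversion paths — none of which
are modelled, so passing tests show internal correctness of this model,
not quantitative prediction for any particular experiment. Mutators are
represented only through a larger `μ`.

## Numerical and design notes

* One generator per replicate (spawned from the master seed) on the
  single-trajectory path; one spawned generator per grid cell on the
  batch path, where all replicates of a cell advance as vectorized
  arrays. Grids are bit-reproducible from the master seed either way.
* Fitness vectors come from the closed forms directly; no accumulation,
  hence no float drift.
* The exact oracle clips sub-epsilon negative pmf values from scipy's
  `exp(logpmf)` and renormalizes rows; it refuses state spaces above
  ~1e5 compositions.
* Trajectory CSVs store only nonzero (class, generation) counts; absent
  pairs are implicitly zero.
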