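# Model and methods

## Overview

`informed_dispersal` is a stochastic, individual-based, female-only
metapopulation model for studying how *informed dispersal* evolves: how
much information individuals should gather before moving (prospecting),
and how emigration itself should respond to personal information (own
breeding outcome) and public information (local conspecific breeding
success, LBS). The life cycle is patterned on long-lived colonial
breeders (seabird-like survival and deferred recruitment), but nothing
in the implementation is species-specific.

The model couples four layers:

1. **Environment.** `n_patches = 25` breeding patches each carry an
   independent environmental quality `Q` following a stationary AR(1)
   process, `Q_{t+1} = α Q_t + w_t √(1−α²)`, `w_t ~ N(0, σ)`, with
   `α = 0.8` and `σ = 1` by default. The `√(1−α²)` scaling keeps the
   marginal variance at `σ²` for every `α`, so predictability can be
   varied without changing fluctuation amplitude. Carrying capacity is
   `K = max(0, K₀ + K₀ Q)` with `K₀ = 100`; `K` is real-valued and `Q`
   itself is never clamped. Temporal autocorrelation is the condition
   that makes this year's breeding success informative about next
   year's prospects; with `α = 0` LBS carries no forward information
   (the test suite verifies the year-to-year LBS correlation tracks
   `α`).

2. **Demography.** The year starts with reproduction: each adult in a
   patch with `N` adults draws offspring from a Poisson with mean
   `Off_max / (1 + (Off_max − 1) N / K)` (`Off_max = 2`), so fecundity
   falls from 2 at zero density through 1 at `N = K`. An adult with ≥ 1
   offspring (raw draw, before any juvenile mortality) is a successful
   breeder; `LBS = successful / N`. Offspring are juveniles (first-year
   survival `S_J = 0.6`), then pre-breeders (`S_I = 0.7`) until a
   recruitment age drawn at birth from Poisson(`R = 5`), floored at 2 so
   every individual spends at least one full year in each immature
   stage; adults survive at `S_A = 0.85`. Pre-breeders neither breed nor
   disperse and do not count toward `N`.

3. **Dispersal.** Emigration, prospecting, and settlement are resolved
   against a *pre-movement snapshot* of occupancy and LBS taken right
   after reproduction, so outcomes are independent of the order in
   which individuals are processed. Emigration probability comes from
   one of three strategies: a single probability `E` (uninformed);
   status-specific `E_succ` / `E_fail` (personal information); or
   status-specific linear reaction norms `β + α_norm · LBS` on the local
   LBS (personal + public), clamped to [0, 1] at use. New recruits have
   no breeding history and use the failed-breeder rule with their natal
   patch's LBS. Emigrants prospect a uniform random subset of
   `min(N_p, 24)` non-natal patches, die with probability
   `M · n_prospected` (`M` = 0 or 0.01), and settle by one of three
   patch-selection processes on the prospected LBS values: proportional
   (`inaccurate`), softmax with coefficient 50 (`accurate`), or argmax
   with uniform ties (`deterministic`). `N_p = 0` (and effectively
   `N_p = 1`) is random settlement. Emigrants never return to the patch
   they just left. Patches that held no adults at the snapshot carry
   LBS 0, so informed settlement virtually never picks them; random
   settlers (`N_p ≤ 1`) and prospectors whose whole sample had zero
   success can settle there, and this is the network's only
   recolonization route. The design choice matters: if settlement were
   restricted to currently occupied patches, empty patches would be
   absorbing and the metapopulation would lose patches monotonically
   until global extinction well inside an evolutionary run — incompatible
   with a model whose results are reported after 20,000 stationary
   years.

4. **Genetics.** Individuals are haploid; each dispersal trait that
   evolves in a scenario is one maternally inherited locus. Mutation is
   per locus, per offspring, with probability `μ = 0.01`: continuous
   alleles gain an `N(0, 0.1)` increment, the discrete `N_p` allele
   steps ±1. Every proposal is clamped to the locus's legal interval —
   probabilities to [0, 1], reaction-norm slopes to [−1, 0], `N_p` to
   0..24. Bounding the continuous alleles is a deliberate design
   choice: allele values beyond the behavioral range are selectively
   invisible (an allele of 1.3 behaves exactly like 1.0), so unbounded
   kernels let alleles diffuse neutrally far outside [0, 1] and the
   population mean allele stops being interpretable as a probability —
   in unbounded trial runs adult means drifted above 1 and below 0.
   Clamping keeps the reported allele means on the scale of the
   evolved probabilities they summarize.

## Annual cycle

Within a year: (1) environment step; (2) reproduction and breeding
status; (3) occupancy/LBS snapshot; (4) dispersal of adults and of this
year's recruits (promotion to adult happens at settlement; recruits
breed for the first time the following year); (5) stage-specific
survival (prospecting deaths are removed here too) and promotion of
surviving juveniles to pre-breeders; (6) ages increment. Global
extinction leaves an empty roster while the environment keeps running.

## Experiments

Both published experiments use a 3 × 3 × 2 grid: three emigration
strategies × three patch-selection processes × prospecting cost
`M ∈ {0, 0.01}`. In the first, only `N_p` evolves and the emigration
parameters are fixed (`E = 0.5`; `E_succ = 0.05`, `E_fail = 0.5`;
`β_succ = 0.05`, `α_succ = 0`, `β_fail = 0.5`, `α_fail = −0.45`). In
the second, the strategy's emigration loci co-evolve with `N_p`.
Founder alleles are uniform on their legal intervals (`N_p` uniform on
0..24). Each patch starts with `K₀` adults of uniform age 2–10; the
demographic transient dies out within decades and is irrelevant on
evolutionary time scales.

## Implementation and numerical choices

- The roster is columnar (NumPy arrays over individuals), not
  object-per-individual; a year costs ~2–3 ms at equilibrium
  (~2,000 adults, ~8,000 individuals), which makes multi-millennia
  runs practical on one core. Non-evolving loci are stored as scalars.
- One master seed per scenario; replicates run on `SeedSequence`
  child streams; within a year all decisions are vectorized draws
  consumed in individual-id order, so identical configurations are
  bit-reproducible and roster permutations cannot change results.
- Prospecting subsets are drawn by ranking i.i.d. uniform keys per
  candidate patch — a uniform subset without replacement, vectorized
  across all emigrants at once.
- The softmax of the accurate process is computed with the max
  subtracted (numerically stable at coefficient 50); settlement
  vectors sum to 1 within 1e−12.
- Degenerate cases: all-zero LBS under the inaccurate process falls
  back to a uniform choice; deterministic ties split uniformly; a
  recruit whose natal patch held no adults at the snapshot reads
  LBS = 0; prospecting cost uses the realized prospected count, so a
  stranded or non-prospecting emigrant pays nothing.
- Prospecting mortality is applied between the emigration decision and
  settlement; recruits dying there never recruit.

## What the simulations do and do not show

All inputs are generated internally; there is no field data anywhere in
the pipeline. The environment emulates temporally predictable local
quality with no spatial structure: patches have no positions, distances
or dispersal costs that depend on geometry, and all patches are
statistically exchangeable. Consequences: results say nothing about
distance-dependent prospecting, perceptual ranges, or spatially
autocorrelated landscapes. Demography omits senescence, males and mate
choice; genetics omits diploidy, recombination and linkage. Agreement
of scaled-down runs with the published equilibria shows the mechanism
is reproduced, not that the model describes any particular field
system.

The headline statistics are stochastic evolutionary equilibria. The
default scaled-down size used by `scripts/acceptance.py` is 8,000
years × 4 replicates per scenario (the published runs are 20,000 × 10);
the test suite uses 6,000 × 3. Trait means plateau within the first few
thousand years in the strongly selected scenarios (accurate or
deterministic selection, or any scenario with prospecting cost); under
*inaccurate* selection with costless prospecting selection on
emigration is weaker and the evolved means keep a slow residual drift,
so those statistics carry cross-replicate spreads of a few hundredths
at any affordable run length.

## Known limitations

- Weakly selected scenarios (see above) converge slowly; increasing
  replicates tightens the cross-replicate mean faster than increasing
  years.
- The engine is serial; replicates are independent and could be run in
  separate processes, but no parallel executor is shipped.
- With very small `K₀` (≪ 20) global extinction becomes common and the
  evolved-trait summaries are conditioned on survival.
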