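# Methods

## The model

`woundabc` simulates a wound-healing (scratch) assay as a continuous-time
exclusion process on a two-dimensional square lattice of `Lx` columns by `Ly`
rows.  Each site holds at most one agent (a cell of side `delta = 26` µm).
Rows are periodic — cells drift in and out of the top and bottom of a
microscope field at roughly equal rates — while columns never wrap: the wound
is horizontal structure and must not be short-circuited.

Every agent attempts a move at rate `Pm` (min⁻¹), so in a population of `N`
agents events occur at total rate `N·Pm`, with exponential waiting times and a
uniformly chosen attempting agent (Gillespie's direct method).  A selected
agent with `n` occupied nearest neighbours moves to a given *available* target
with probability

* model A (linear):      `T_A(n) = (1 − n·α)/4`
* model B (geometric):   `T_B(n) = (1 − α)^n / 4`

and otherwise stays put; failed attempts still consume the event.  `α > 0`
is adhesion (occupied neighbours suppress movement), `α < 0` repulsion.
Requiring every `T(n) ≥ 0` and the summed probability over the `u` available
targets `u·T(n) ≤ 1` for all `n`, `u ≤ 4 − n` bounds the admissible parameter:
`α ∈ [−1/3, 1/4]` for model A and `α ∈ [−1/3, 1]` for model B.  The uniform
priors used for inference, `α ∈ [−0.2, 0.25]` (A) and `α ∈ [−0.2, 1]` (B) with
`Pm ∈ [0, 1]`, are strict subsets of these ranges.

A note on the event scheme: the narrative "pick one of four directions, then
accept with probability `4T`" is only a valid sampling scheme when `4T ≤ 1`,
which fails for repulsion (model A, `α = −0.2`, `n = 2` gives `4T = 1.4`).
The admissibility inequalities bound only the sum over *available* targets, so
the implementation draws the event outcome directly from that distribution:
success with probability `u·T(n)`, target uniform among the `u` available
ones.  Where both schemes are proper they are exactly equivalent.

### Boundary handling and replenishment

Closed (`no_flux`) columns simply make the off-domain direction unavailable;
the neighbour count `n` never includes off-lattice positions and the
denominator in `T` stays 4.  Open (`flux`) columns treat the off-domain
direction as an always-empty target: an agent selecting it leaves the
simulation (its record is kept so displacement can exclude it).  The realistic
assay keeps the left-most column at or above a target density, emulating the
bulk cell reservoir behind the field of view: after any movement event that
vacates a column-1 site, empty column-1 sites are filled uniformly at random
until the column again holds `ceil(density·Ly)` agents.  The target density
defaults to the design's initial column-1 density (1.0 for the bundled
profile); the value used in the original experiment is not published, so it is
configurable.  Replenishment is triggered only by successful vacating moves,
and a vertical move within column 1 does not trigger it (the column count is
unchanged).

One degenerate geometry is handled explicitly: on an `Ly = 1` lattice a
periodic vertical neighbour would be the site itself, so single-row lattices
have no vertical moves and the agent's own site never counts toward `n`.
This keeps one-row strips faithful to the continuous-time random walk they
are meant to represent (and makes them usable as exact test oracles).
`Ly = 2` keeps the usual periodic convention: up and down reach the same site
and are counted twice.

### Two kernels, one process

The simulator compiles two numba kernels.  On closed domains the population —
and hence the total event rate — is constant, so the number of events in each
inter-snapshot interval is Poisson(`N·Pm·Δt`) and no per-event clock is
needed.  On open domains (flux and/or replenishment) the rate changes with
`N` and the kernel tracks exponential waiting times.  Both are exact
realisations of the same Markov process; the closed-domain path is roughly
2–3× faster, which matters because ABC spends almost all of its time here.
Agent capacity for replenishing runs is pre-allocated from a generous bound on
the expected number of additions; if a run exceeds it the kernel reports
overflow and the wrapper deterministically reruns with a doubled registry.

## Initial conditions

* **Idealised double-sided wound** (`unrealistic` preset, 100×100 by default):
  columns 1–10 and `Lx−9..Lx` fully occupied, deterministic.  Scaled-down
  variants (e.g. 50×50 in the acceptance studies) keep the fixed 10-column
  blocks.
* **Single-sided wound** (`realistic_*` presets, 23×23 and 23×184): agents are
  placed per column by rounding `density_i·Ly` and sampling rows without
  replacement.  The bundled density profile — six full columns, then a linear
  ramp to zero over three columns — is a synthetic stand-in for the
  experiment-derived average profile, which is not published in usable form;
  a measured profile can be passed as a CSV/vector instead.  Domain scaling
  for design studies multiplies `Ly` while keeping the column densities
  fixed, which is how a wider microscope field of view is emulated.

## Summary statistics

At sampling times `t = 240, 480, 720` min (4, 8, 12 h):

* **Average horizontal displacement** — mean over agents of `|i(t_i) − i(t_f)|`
  in lattice-site units, with `t_i = 0` by default.  Only agents present at
  both times contribute; flux leavers and replenishment arrivals are excluded
  (on closed domains this equals the all-agent average).
* **Density profile** `C_t(i)` — occupied fraction per column.
* **Pair-correlation function** `q_t(m) = c_t(m)/ĉ_t(m)` for
  `m = 1..Lx−1`, where `c_t(m)` counts unordered agent pairs at horizontal
  separation `m` (columns only, never wrapping) and
  `ĉ_t(m) = Ly²(Lx−m)·ρ·ρ̂` with `ρ = N/(LxLy)`, `ρ̂ = (N−1)/(LxLy−1)` is the
  expectation under uniformly random placement of the same `N` agents.
  `q ≡ 1` means no horizontal structure.  Same-column pairs (`m = 0`) are
  excluded from `q` but exposed via `same_column_pairs`, so the identity
  `Σ_m c_t(m) + same-column pairs = N(N−1)/2` can be (and is) checked.

A synthetic dataset runs `n_replicates` independent simulations (replicate
`r` seeded `seed + r`), evaluates all statistics at each time, and keeps both
the per-replicate values and their ensemble averages.  Ensemble variances use
the unbiased (`n−1`) estimator, appropriate for the small replicate counts
(5–10) that the assay designs prescribe.

## Inference

The ABC distance is the L1 difference of ensemble-averaged statistics,
`d = Σ_t Σ_r |S(D)_{r,t} − S(D̃)_{r,t}|`, over the selected statistics and
times (per-statistic weights default to 1; when statistics are combined the
recommended weights are inverse pilot-run medians, since the three statistics
live on different scales).

* **Rejection**: draw `n_sims` iid `Θ = (Pm, α)` from the uniform prior box,
  simulate the design once per draw, keep the `n_accept` smallest distances
  (ties by draw order).  One simulation per draw is the standard scheme — the
  observed side is an ensemble average, the simulated side a single noisy
  realisation; `n_replicates_sim` lets each simulated dataset be averaged over
  replicates instead (e.g. to mirror the observed protocol), at
  proportionally higher cost.  All summary statistics are recorded per
  simulation, so several distance specifications can share one simulation
  batch (`abc_rejection_multi`) — this is how the statistic-ranking study
  avoids triplicating its compute.
* **MCMC**: Marjoram-style chain with a symmetric Gaussian random-walk kernel
  (default scales 5% of each prior width, default start at the box centre).
  Proposals outside the box are rejected outright — equivalent to prior
  truncation under a uniform prior — otherwise the design is simulated at the
  proposal and the move is accepted iff `d ≤ ε`; on rejection the chain
  repeats its state.  The published analysis does not state its kernel,
  threshold or chain length, so all are exposed; `choose_epsilon` supplies the
  default `ε` as the 1% nearest-rank quantile of a pilot rejection run.

## Posterior analysis

Samples are discretised onto a 2⁶×2⁶ grid of equal-width bins spanning the
prior box (half-open bins, last bin closed).  The prior grid is the exact
uniform `1/4096` — the prior is known, so it is never estimated.  The
information gain is `D_KL(p‖π) = Σ_l p_l log(p_l/π_l)` with `0·log 0 = 0`,
reported in nats (`base=2` gives bits; the published values do not state their
log base, so the switch supports sensitivity checks).

Two estimator choices matter at small sample sizes:

* **Histogram vs KDE.**  The default discretisation is the raw normalised
  histogram.  With `n_accept` far below 4096 bins, however, nearly every
  accepted sample lands in its own cell and the histogram KLD saturates near
  `log(4096/n)` regardless of how concentrated the posterior is — it measures
  the sample size, not the information gain.  `discretize_posterior(...,
  smooth=True)` therefore evaluates a Gaussian KDE at the cell centres
  (renormalised over the box); the desk-scale statistic-ranking and
  design-comparison studies use this estimator, and it is also the only way a
  25-sample posterior can produce divergences on the scale of the published
  single-digit values.
* **Mode.**  The argmax of a 64×64 histogram of 25 samples is tie-ridden, so
  the reported posterior mode is the accepted sample that maximises a
  Gaussian KDE over the accepted set (componentwise median as the degenerate
  fallback).

## Design studies

`variance_study` reports, per (domain, replicate-count) cell, either the
across-replicate sample variance of the statistic as a `k`-replicate
experiment would estimate it (`kind="replicate"`, the default — the spread
visible in a single experiment, where the replicate count only sets the
estimator's quality) or the dataset-to-dataset variance of the ensemble
average across independently regenerated datasets (`kind="ensemble"`, which
shrinks like `1/n_rep` and is the noise the ABC distance actually sees).
Either way the domain size is the dominant lever for the PCF: enlarging the
field multiplies the number of contributing agent pairs — of order
`N(N−1)/2` — and the per-replicate PCF variance drops accordingly, so five
replicates on the 23×184 domain exhibit less variance than even hundreds of
replicates can reveal on 23×23.

`compare_designs` runs the full pipeline per arm — synthetic data at the true
`Θ`, the configured ABC sampler, discretisation, KLD from the prior — and
tabulates KLD, posterior mode and mode error.  Arm seed streams are derived
from the master seed *and the arm's content*, so identical arms reproduce each
other exactly while distinct arms are independent.

## Problem sizes used by the test suite and acceptance script

Full-scale runs of the published analysis (10⁴ rejection simulations on
100×100; multi-day MCMC chains for the realistic designs) are not meaningful
interactive checks, so the bundled studies use scaled-down counterparts chosen
once and kept fixed:

* parameter recovery and statistic ranking: 50×50 idealised wound, truth
  `Θ* = (0.5, 0.1)` in model A, 10-replicate observed data, 500 prior draws,
  25 accepted, three seeds with majority verdicts;
* design comparison: 23×23 with 50 replicates vs 23×92 with 5 replicates,
  150 draws / 15 accepted per arm, three seeds;
* variance ordering: 5 replicates on 23×184 vs 100 replicates on 23×23,
  10 regenerated datasets per cell;
* simulator oracles: single-agent 3-site strip and two adhesive agents on a
  4-site strip against the matrix exponential of the exactly enumerated
  generator (10⁴ runs, total-variation tolerance 0.02).

## What the synthetic data does and does not emulate

The generator reproduces the geometry, boundary behaviour, sampling times and
replicate counts of the assay, but idealises everything biological: constant
per-cell parameters, no proliferation, death, cell-cycle state or chemotaxis,
a deterministic or density-ramp initial profile rather than segmented images,
and a replenishment density that stands in for the unpublished experimental
value.  Passing tests therefore demonstrate that the *inference machinery*
behaves as claimed on data whose generating process is exactly the model —
they do not show that the model captures any particular cell line, nor do
they calibrate `α` against real images.

## Known limitations

* The KLD of a raw small-sample histogram is dominated by sample size (see
  above); published-magnitude divergences require the KDE estimator.
* Identification of weak repulsion (`α` slightly below 0) is poor at desk
  scale, mirroring the published finding that small `|α|` has little effect
  on the dynamics.
* At the desk-scale budgets (50×50 domain, 500 prior draws, 25 accepted) the
  PCF's information-gain advantage over the density profile is within
  seed-to-seed noise — the two KLDs typically differ by ~0.1 nats with the
  sign flipping across seeds, while PCF-vs-displacement and the recovery of
  the truth itself are stable.  Resolving that ranking reliably requires the
  full-scale budget.
* The MCMC variant is a plain Marjoram chain; no sequential ABC, regression
  adjustment or summary-statistic selection is provided.
* Displacement requires agents present at both ends of the interval; on open
  domains with heavy turnover the effective `N'` can be much smaller than
  `N`, and the statistic is undefined if no agent survives the interval.
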