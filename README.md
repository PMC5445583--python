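# woundabc

Simulation-based design and inference for wound-healing (scratch) assays.

A scratch assay watches cells migrate into a cleared region; it is the
standard bench experiment for quantifying cell motility, and — when cell-cell
adhesion or repulsion matters — the interactions that modulate it.  `woundabc`
asks the question a modeller planning such an experiment needs answered:
*given this experimental design, can the motility and adhesion parameters be
identified at all, and which design changes help?*

It provides:

* an exact continuous-time **agent-based model**: agents on an `Lx × Ly`
  square lattice with volume exclusion (one agent per site), periodic rows,
  closed or open columns, and movement attempts at rate `Pm` modulated by the
  occupied-neighbour count `n` through one of two adhesion models,

  `T_A(n) = (1 − nα)/4` (linear)  or  `T_B(n) = (1 − α)^n / 4` (geometric),

  with `α > 0` adhesion and `α < 0` repulsion;
* the three **summary statistics** used to compare datasets: average
  horizontal displacement, per-column density profile, and the
  volume-exclusion-normalised pair-correlation function (PCF)
  `q_t(m) = c_t(m) / [Ly²(Lx−m) ρ ρ̂]`;
* **approximate Bayesian computation** for `Θ = (Pm, α)`: rejection sampling
  (keep the draws with the smallest L1 distance between ensemble-averaged
  statistics) and a Marjoram-style ABC-MCMC chain;
* **design comparison** via the Kullback–Leibler divergence
  `D_KL(p‖π) = Σ_l p_l log(p_l/π_l)` of the discretised (2⁶ × 2⁶) posterior
  from the uniform prior — more nats, more information gained about `Θ`;
* three bundled experiment presets: the idealised double-sided wound
  (100×100, closed), the practically realisable single-sided assay (23×23
  sites of 26 µm, open columns with a replenished left edge, 5 replicates),
  and its enlarged variant (23×184, an eight-fold larger field of view).

The headline result the package reproduces at desk scale: because the PCF is
built from `N(N−1)/2` agent pairs, enlarging the domain (more agents) shrinks
its sampling variance far faster than adding replicates — five replicates on
a domain eight times larger beat hundreds of replicates on the small domain
for parameter identification.

## Worked example

Generate synthetic data for the realisable assay at a known truth, then try
to re-identify the parameters with rejection ABC on the idealised design:

```sh
$ woundabc synth --design realistic_small --model B --pm 0.5 --alpha 0.25 \
    --seed 1 --out runs/synth.csv
wrote 5-replicate dataset to runs/synth.csv

$ woundabc abc-reject --design unrealistic --lx 50 --ly 50 --replicates 10 \
    --model A --pm 0.5 --alpha 0.1 --n-sims 500 --n-accept 25 --seed 1 \
    --out runs/posterior.csv
accepted 25/500; KLD vs prior = 5.0989 nats; wrote runs/posterior.csv
```

The second command simulates 10-replicate observed data at the truth
`Θ* = (0.5, 0.1)`, draws 500 parameter pairs from the uniform prior
(`Pm ∈ [0,1]`, `α ∈ [−0.2, 0.25]` for model A), simulates each once, and
keeps the 25 draws whose PCF is closest to the observed ensemble average.
The reported divergence compares the raw 64×64 histogram of those 25 samples
with the uniform prior; `runs/posterior.csv` holds the accepted `(Pm, α, d)`
rows and `runs/posterior.csv.json` the full provenance.  In Python:

```python
>>> import woundabc as w
>>> from woundabc.io import read_posterior_csv
>>> samples, _, _ = read_posterior_csv("runs/posterior.csv")
>>> w.posterior_mode(samples).round(3)
array([0.574, 0.138])
```

— within 0.08 of the truth on both coordinates for this seed.  Other
subcommands: `simulate` (occupancy snapshots as CSV), `abc-mcmc`, `kld`,
`variance`, and `compare-designs`, e.g.

```sh
woundabc compare-designs --arm 23x23x50 --arm 23x92x5 --n-sims 150 --n-accept 15
```

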