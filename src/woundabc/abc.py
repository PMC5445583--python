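"""Approximate Bayesian computation: distance, rejection sampling, and MCMC.

Likelihood-free inference for Theta = (Pm, alpha): simulate the experiment
design at proposed parameters, summarise, and compare to the observed summary
statistics through the L1 distance

    d = sum_t sum_r | S(D)_{r,t} - S(D~)_{r,t} |,

summed over sampling times t and the entries r of each selected statistic
vector (ensemble averages on both sides).  Rejection keeps the ``n_accept``
parameter draws with the smallest distances; the MCMC variant is a
Marjoram-style chain with a symmetric Gaussian random-walk kernel, uniform
priors (so the Metropolis ratio inside the box is one) and acceptance
``d <= epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .designs import ExperimentDesign, generate_synthetic_data
from .lattice import ModelParams, admissible_alpha_range
from .summaries import STATISTICS, SummaryDataset

__all__ = [
    "PriorBox",
    "DistanceSpec",
    "PosteriorResult",
    "distance",
    "abc_rejection",
    "abc_rejection_multi",
    "abc_mcmc",
    "choose_epsilon",
]


@dataclass(frozen=True)
class PriorBox:
    """Independent uniform priors for Pm and alpha, tied to an adhesion model.

    The standard boxes are ``Pm in [0, 1]`` with ``alpha in
    [-0.2, 0.25]`` for model A and ``alpha in [-0.2, 1.0]`` for model B; any
    box must stay inside the admissible alpha range of its model.
    """

    pm_bounds: tuple[float, float] = (0.0, 1.0)
    alpha_bounds: tuple[float, float] | None = None
    model: str = "A"

    def __post_init__(self) -> None:
        if self.alpha_bounds is None:
            default = {"A": (-0.2, 0.25), "B": (-0.2, 1.0)}[self.model]
            object.__setattr__(self, "alpha_bounds", default)
        for lo, hi in (self.pm_bounds, self.alpha_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("prior bounds must be finite with lower < upper")
        if self.pm_bounds[0] < 0:
            raise ValueError("Pm prior must be non-negative")
        a_lo, a_hi = admissible_alpha_range(self.model)
        if self.alpha_bounds[0] < a_lo or self.alpha_bounds[1] > a_hi:
            raise ValueError(
                f"alpha prior {self.alpha_bounds} exceeds the admissible range "
                f"[{a_lo:.6g}, {a_hi:.6g}] for model {self.model}"
            )

    def contains(self, theta: Sequence[float]) -> bool:
        pm, alpha = theta
        return (self.pm_bounds[0] <= pm <= self.pm_bounds[1]
                and self.alpha_bounds[0] <= alpha <= self.alpha_bounds[1])

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw ``size`` iid Theta from the uniform box, shape (size, 2)."""
        pm = rng.uniform(*self.pm_bounds, size=size)
        alpha = rng.uniform(*self.alpha_bounds, size=size)
        return np.column_stack([pm, alpha])

    def widths(self) -> np.ndarray:
        return np.array([
            self.pm_bounds[1] - self.pm_bounds[0],
            self.alpha_bounds[1] - self.alpha_bounds[0],
        ])

    def params(self, theta: Sequence[float]) -> ModelParams:
        return ModelParams(Pm=float(theta[0]), alpha=float(theta[1]), model=self.model)


@dataclass(frozen=True)
class DistanceSpec:
    """Which statistics and sampling times enter the ABC distance, with weights."""

    statistics: tuple[str, ...] = ("pcf",)
    times: tuple[float, ...] = (240.0, 480.0, 720.0)
    weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.statistics:
            raise ValueError("at least one statistic is required")
        for s in self.statistics:
            if s not in STATISTICS:
                raise ValueError(f"unknown statistic {s!r}")
        if not self.times:
            raise ValueError("at least one sampling time is required")
        w = dict(self.weights or {})
        for s in self.statistics:
            w.setdefault(s, 1.0)
            if w[s] <= 0:
                raise ValueError(f"weight for {s!r} must be positive")
        object.__setattr__(self, "weights", w)


@dataclass
class PosteriorResult:
    """Accepted samples (rejection) or a chain (MCMC) plus provenance.

    ``samples`` are the accepted Theta (rejection) or all chain states (MCMC);
    ``distances`` align with ``samples``.  For rejection runs ``all_samples``
    and ``all_distances`` retain the full prior batch (useful as an epsilon
    pilot); for MCMC ``accepted`` flags proposal acceptance per step.
    """

    samples: np.ndarray
    distances: np.ndarray
    prior: PriorBox
    spec: DistanceSpec
    seed: int
    method: str
    all_samples: np.ndarray | None = None
    all_distances: np.ndarray | None = None
    accepted: np.ndarray | None = None
    epsilon: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def acceptance_rate(self) -> float:
        if self.accepted is None:
            raise ValueError("acceptance rate is only defined for MCMC results")
        return float(np.mean(self.accepted))


def distance(observed: SummaryDataset, simulated: SummaryDataset, spec: DistanceSpec) -> float:
    """L1 distance between ensemble-averaged summary statistics (weighted per statistic)."""
    d = 0.0
    for name in spec.statistics:
        w = spec.weights[name]
        for t in spec.times:
            try:
                a = observed.mean(name, t)
                b = simulated.mean(name, t)
            except KeyError as exc:
                raise ValueError(f"dataset missing statistic ({name}, t={t})") from exc
            if a.shape != b.shape:
                raise ValueError(
                    f"shape mismatch for ({name}, t={t}): {a.shape} vs {b.shape}"
                )
            d += w * float(np.abs(a - b).sum())
    return d


def _simulate_batch(design, prior, n_sims, n_replicates_sim, statistics, seed):
    """Draw n_sims Theta from the prior and simulate one dataset per draw."""
    rng = np.random.default_rng(seed)
    thetas = prior.sample(rng, n_sims)
    sim_seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    datasets = []
    for i in range(n_sims):
        params = prior.params(thetas[i])
        datasets.append(generate_synthetic_data(
            design, params, n_replicates=n_replicates_sim,
            seed=int(sim_seeds[i]), statistics=statistics,
        ))
    return thetas, datasets


def abc_rejection_multi(
    design: ExperimentDesign,
    prior: PriorBox,
    observed: SummaryDataset,
    specs: Mapping[str, DistanceSpec],
    n_sims: int,
    n_accept: int,
    seed: int = 0,
    n_replicates_sim: int | None = None,
) -> dict[str, PosteriorResult]:
    """Rejection ABC for several distance specs sharing one simulation batch.

    The expensive part of rejection ABC is simulating the prior draws; every
    spec (e.g. one per summary statistic) can reuse the same batch because the
    simulations record all statistics.  Each prior draw is simulated once by
    default (``n_replicates_sim`` overrides).  Returns one PosteriorResult per
    spec key.  Ties in the distance are broken by draw order.
    """
    if n_accept > n_sims:
        raise ValueError(f"n_accept={n_accept} exceeds n_sims={n_sims}")
    if n_replicates_sim is None:
        n_replicates_sim = 1
    needed = tuple(dict.fromkeys(s for spec in specs.values() for s in spec.statistics))
    thetas, datasets = _simulate_batch(design, prior, n_sims, n_replicates_sim, needed, seed)
    results = {}
    for key, spec in specs.items():
        dists = np.array([distance(observed, ds, spec) for ds in datasets])
        order = np.argsort(dists, kind="stable")[:n_accept]
        results[key] = PosteriorResult(
            samples=thetas[order], distances=dists[order], prior=prior, spec=spec,
            seed=int(seed), method="rejection",
            all_samples=thetas, all_distances=dists,
            meta={"n_sims": int(n_sims), "n_accept": int(n_accept),
                  "n_replicates_sim": int(n_replicates_sim), "design": design.name},
        )
    return results


def abc_rejection(
    design: ExperimentDesign,
    prior: PriorBox,
    observed: SummaryDataset,
    spec: DistanceSpec,
    n_sims: int,
    n_accept: int,
    seed: int = 0,
    n_replicates_sim: int | None = None,
) -> PosteriorResult:
    """Rejection ABC: keep the ``n_accept`` prior draws with the smallest distances.

    Each of the ``n_sims`` prior draws is simulated once (``n_replicates_sim=1``,
    the standard scheme); pass a larger value to average each simulated dataset
    over replicates, e.g. to mirror the observed data's replicate protocol.
    """
    return abc_rejection_multi(
        design, prior, observed, {"only": spec}, n_sims, n_accept, seed,
        n_replicates_sim,
    )["only"]


def abc_mcmc(
    design: ExperimentDesign,
    prior: PriorBox,
    observed: SummaryDataset,
    spec: DistanceSpec,
    epsilon: float = None,
    chain_length: int = 1000,
    proposal_scales: Sequence[float] | None = None,
    seed: int = 0,
    theta0: Sequence[float] | None = None,
    n_replicates_sim: int | None = None,
) -> PosteriorResult:
    """ABC-MCMC with a symmetric Gaussian random-walk kernel.

    At each step a proposal ``Theta' = Theta + N(0, diag(scales^2))`` is drawn;
    proposals outside the prior box are rejected outright, otherwise the design
    is simulated at ``Theta'`` and the move is accepted iff the distance to the
    observed data is at most ``epsilon`` (uniform priors make the Metropolis
    ratio one inside the box).  On rejection the chain repeats the current
    state.  Default proposal scales are 5% of each prior width; the default
    start is the box centre.
    """
    if epsilon is None or not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon!r}")
    if chain_length < 1:
        raise ValueError("chain_length must be at least 1")
    widths = prior.widths()
    scales = np.asarray(proposal_scales, float) if proposal_scales is not None else 0.05 * widths
    if scales.shape != (2,) or (scales < 0).any():
        raise ValueError("proposal_scales must be two non-negative numbers")
    theta = (np.asarray(theta0, float) if theta0 is not None
             else np.array([np.mean(prior.pm_bounds), np.mean(prior.alpha_bounds)]))
    if not prior.contains(theta):
        raise ValueError(f"initial Theta {theta} lies outside the prior box")
    if n_replicates_sim is None:
        n_replicates_sim = 1

    rng = np.random.default_rng(seed)
    current_d = np.inf
    chain = np.empty((chain_length, 2))
    dists = np.empty(chain_length)
    accepted = np.zeros(chain_length, dtype=bool)
    for step in range(chain_length):
        proposal = theta + rng.normal(0.0, 1.0, size=2) * scales
        if prior.contains(proposal):
            sim_seed = int(rng.integers(0, 2**31 - 1))
            sim = generate_synthetic_data(
                design, prior.params(proposal), n_replicates=n_replicates_sim,
                seed=sim_seed, statistics=spec.statistics,
            )
            d = distance(observed, sim, spec)
            if d <= epsilon:
                theta = proposal
                current_d = d
                accepted[step] = True
        chain[step] = theta
        dists[step] = current_d
    return PosteriorResult(
        samples=chain, distances=dists, prior=prior, spec=spec, seed=int(seed),
        method="mcmc", accepted=accepted, epsilon=float(epsilon),
        meta={"chain_length": int(chain_length), "proposal_scales": scales.tolist(),
              "n_replicates_sim": int(n_replicates_sim), "design": design.name},
    )


def choose_epsilon(pilot: PosteriorResult, quantile: float) -> float:
    """Nearest-rank empirical quantile of a pilot run's distances.

    ``quantile`` must lie strictly between 0 and 1... the nearest-rank rule
    returns the ``ceil(q * n)``-th smallest distance (so quantile 0.5 of three
    distances is the median, and any quantile below 1/n gives the smallest).
    """
    dists = pilot.all_distances if pilot.all_distances is not None else pilot.distances
    if dists is None or len(dists) == 0:
        raise ValueError("pilot result contains no distances")
    if not (0.0 < quantile <= 1.0):
        raise ValueError(f"quantile must lie in (0, 1], got {quantile}")
    s = np.sort(np.asarray(dists, float))
    rank = int(np.ceil(quantile * s.size))
    return float(s[max(rank, 1) - 1])
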