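"""Shared fixtures: CTMC oracle runs and the scaled-down ABC recovery batches.

The expensive simulation batches are session-scoped so the parameter-recovery,
statistic-ranking and ridge checks all reuse one set of prior-predictive
simulations per seed.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import woundabc as w

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

RECOVERY_TRUTH = w.ModelParams(Pm=0.5, alpha=0.1, model="A")
RECOVERY_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def strip_ctmc_tv():
    """Total-variation distance between simulated and exact single-agent dynamics.

    A single agent on a 3-site no-flux strip (1 row, so no vertical moves and
    no occupied neighbours) is a 3-state continuous-time Markov chain with hop
    rate Pm/4 per available direction; the exact time-t occupancy distribution
    is the matrix exponential of the generator.  Compares against the
    empirical distribution over 10^4 simulation runs.
    """
    from scipy.linalg import expm

    pm, t = 0.8, 3.0
    domain = w.LatticeDomain(3, 1, x_boundary="no_flux")
    params = w.ModelParams(Pm=pm, alpha=0.1, model="A")
    initial = w.OccupancyState(3, 1, ids=[0], col=[1], row=[1])

    rate = pm / 4.0
    gen = rate * np.array([[-1.0, 1.0, 0.0], [1.0, -2.0, 1.0], [0.0, 1.0, -1.0]])
    exact = expm(gen * t)[0]

    n_runs = 10_000
    counts = np.zeros(3)
    for s in range(n_runs):
        rec = w.gillespie_run(domain, params, initial, [t], seed=s)
        counts[rec.state_at(t).col[0] - 1] += 1
    empirical = counts / n_runs
    return 0.5 * float(np.abs(empirical - exact).sum())


def _recovery_batch(seed: int):
    """One scaled-down recovery experiment: 50x50 double-sided wound, truth (0.5, 0.1).

    Generates 10-replicate observed data at the truth, then rejection ABC with
    500 prior draws / 25 accepted, sharing the simulation batch across the
    three summary statistics.
    """
    design = w.unrealistic_design(50, 50, n_replicates=10)
    prior = w.PriorBox(model="A")
    observed = w.generate_synthetic_data(design, RECOVERY_TRUTH, seed=seed * 1000 + 17)
    specs = {
        s: w.DistanceSpec(statistics=(s,), times=design.times)
        for s in w.STATISTICS
    }
    return w.abc_rejection_multi(
        design, prior, observed, specs, n_sims=500, n_accept=25,
        seed=seed * 1000 + 613,
    )


@pytest.fixture(scope="session")
def recovery_batches():
    """Rejection-ABC results per summary statistic for three independent seeds."""
    return [_recovery_batch(s) for s in RECOVERY_SEEDS]
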