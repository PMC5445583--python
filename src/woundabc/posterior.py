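"""Discretised posteriors and Kullback-Leibler divergence from the prior.

Posterior samples (accepted rejection draws or MCMC chain states) are binned
onto a 2^6 x 2^6 grid of equally spaced (Pm, alpha) values spanning the prior
box; the information gained over the uniform prior is then

    D_KL(p | pi) = sum_l p_l log(p_l / pi_l),    0 log 0 := 0,

reported in nats by default (``base=2`` gives bits, used for log-base
sensitivity checks).  The prior grid is the exact uniform 1/4096 -- the prior
is known analytically, so it is never estimated from samples.
"""

from __future__ import annotations

import numpy as np

from .abc import PriorBox

__all__ = [
    "GRID_SIZE",
    "GridPosterior",
    "discretize_posterior",
    "uniform_prior_grid",
    "kld",
    "posterior_mode",
]

GRID_SIZE = 64  # 2**6 bins per parameter


class GridPosterior:
    """A normalised probability mass function on the discretised prior box.

    ``grid[a, b]`` is the mass of the (Pm-bin a, alpha-bin b) cell; bins are
    equal-width and half-open with the last bin closed.
    """

    def __init__(self, grid: np.ndarray, pm_edges: np.ndarray, alpha_edges: np.ndarray) -> None:
        grid = np.asarray(grid, dtype=float)
        if grid.shape != (pm_edges.size - 1, alpha_edges.size - 1):
            raise ValueError("grid shape does not match bin edges")
        if (grid < 0).any():
            raise ValueError("grid entries must be non-negative")
        total = grid.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"grid mass must sum to 1, got {total!r}")
        self.grid = grid
        self.pm_edges = np.asarray(pm_edges, dtype=float)
        self.alpha_edges = np.asarray(alpha_edges, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def same_grid(self, other: "GridPosterior") -> bool:
        return (np.array_equal(self.pm_edges, other.pm_edges)
                and np.array_equal(self.alpha_edges, other.alpha_edges))


def _edges(prior: PriorBox, bins: int) -> tuple[np.ndarray, np.ndarray]:
    return (np.linspace(*prior.pm_bounds, bins + 1),
            np.linspace(*prior.alpha_bounds, bins + 1))


def discretize_posterior(samples: np.ndarray, prior: PriorBox, bins: int = GRID_SIZE,
                         smooth: bool = False) -> GridPosterior:
    """Discretise (Pm, alpha) samples onto the prior box.

    By default a raw normalised 2-D histogram.  With ``smooth=True`` the cell
    masses come from a Gaussian KDE of the samples evaluated at the cell
    centres (and renormalised over the box) -- the appropriate estimator when
    the number of accepted samples is far below the number of grid cells, where
    a raw histogram saturates at one sample per cell and its divergence from
    the prior no longer reflects how concentrated the posterior is.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] == 0:
        raise ValueError("samples must be a non-empty (n, 2) array of (Pm, alpha)")
    for theta in samples:
        if not prior.contains(theta):
            raise ValueError(f"sample {theta} lies outside the prior box")
    pm_edges, alpha_edges = _edges(prior, bins)
    if smooth:
        from scipy.stats import gaussian_kde

        centres_pm = (pm_edges[:-1] + pm_edges[1:]) / 2
        centres_al = (alpha_edges[:-1] + alpha_edges[1:]) / 2
        X, Y = np.meshgrid(centres_pm, centres_al, indexing="ij")
        try:
            dens = gaussian_kde(samples.T)(np.vstack([X.ravel(), Y.ravel()]))
        except np.linalg.LinAlgError:
            # degenerate sample cloud: fall back to the raw histogram
            return discretize_posterior(samples, prior, bins, smooth=False)
        grid = dens.reshape(bins, bins)
        return GridPosterior(grid / grid.sum(), pm_edges, alpha_edges)
    hist, _, _ = np.histogram2d(samples[:, 0], samples[:, 1], bins=[pm_edges, alpha_edges])
    return GridPosterior(hist / hist.sum(), pm_edges, alpha_edges)


def uniform_prior_grid(prior: PriorBox, bins: int = GRID_SIZE) -> GridPosterior:
    """The exact uniform prior mass function, 1/bins^2 per cell."""
    pm_edges, alpha_edges = _edges(prior, bins)
    return GridPosterior(np.full((bins, bins), 1.0 / bins**2), pm_edges, alpha_edges)


def kld(posterior: GridPosterior, prior: GridPosterior, base: float | str = "e") -> float:
    """Kullback-Leibler divergence of the posterior from the prior on a shared grid.

    Nats by default; pass ``base=2`` for bits.  Errors if the posterior puts
    mass where the prior has none (the divergence would be infinite).
    """
    if not posterior.same_grid(prior):
        raise ValueError("posterior and prior are discretised on different grids")
    p = posterior.grid
    q = prior.grid
    support = p > 0
    if (q[support] <= 0).any():
        raise ValueError("posterior has mass on a zero-prior bin; KLD is infinite")
    val = float(np.sum(p[support] * np.log(p[support] / q[support])))
    if base in ("e", None):
        return val
    return val / float(np.log(float(base)))


def posterior_mode(samples: np.ndarray) -> np.ndarray:
    """Mode estimate: the sample maximising a Gaussian KDE over the sample cloud.

    Falls back to the componentwise median when the KDE is degenerate (too few
    or collinear samples).
    """
    from scipy.stats import gaussian_kde

    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] == 0:
        raise ValueError("samples must be a non-empty (n, 2) array")
    try:
        kde = gaussian_kde(samples.T)
        dens = kde(samples.T)
        return samples[int(np.argmax(dens))].copy()
    except np.linalg.LinAlgError:
        return np.median(samples, axis=0)
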