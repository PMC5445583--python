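"""Lattice domain, agent state, and the two cell-cell adhesion models.

The simulation takes place on a two-dimensional square lattice with at most
one agent per site (an exclusion process).  Columns are indexed ``i = 1..Lx``
and rows ``j = 1..Ly``; the row direction is periodic (agents wrap top to
bottom), the column direction never wraps.  Agent movement is modulated by the
number ``n`` of occupied nearest-neighbour sites through one of two transition
models:

* model A (linear):      T_A(n) = (1 - n*alpha) / 4
* model B (geometric):   T_B(n) = (1 - alpha)**n / 4

``alpha > 0`` models cell-cell adhesion (movement suppressed next to
neighbours), ``alpha < 0`` repulsion.  For either model the probability that a
selected agent attempts a move to any of its unoccupied neighbours must stay
within [0, 1], which bounds the admissible range of ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MODELS",
    "LatticeDomain",
    "ModelParams",
    "OccupancyState",
    "admissible_alpha_range",
    "transition_probability",
    "initialize_unrealistic",
    "initialize_from_column_densities",
    "replenish_left_column",
]

MODELS = ("A", "B")

#: admissible adhesion-parameter intervals [alpha_min, alpha_max] per model.
#: Model A: T_A(n) >= 0 for every n in 0..4 forces alpha <= 1/4 (binding at
#: n = 4), and u * T_A(n) <= 1 over all (n, u <= 4 - n) forces alpha >= -1/3
#: (binding at n = 1, u = 3).  Model B: (1 - alpha)**n >= 0 for odd n forces
#: alpha <= 1; the sum bound again binds at n = 1, u = 3, giving alpha >= -1/3.
_ALPHA_RANGE = {"A": (-1.0 / 3.0, 0.25), "B": (-1.0 / 3.0, 1.0)}


def _check_model(model: str) -> str:
    if model not in MODELS:
        raise ValueError(f"unknown adhesion model {model!r}; expected one of {MODELS}")
    return model


def admissible_alpha_range(model: str) -> tuple[float, float]:
    """Largest interval of ``alpha`` keeping all movement probabilities in [0, 1].

    For every occupied-neighbour count ``n`` in 0..4 and every number of
    unoccupied targets ``u <= 4 - n``, both ``T(n) >= 0`` and
    ``u * T(n) <= 1`` must hold.
    """
    return _ALPHA_RANGE[_check_model(model)]


def transition_probability(model: str, alpha: float, n: int) -> float:
    """Per-target movement probability ``T(n)`` for an agent with ``n`` occupied neighbours.

    Parameters
    ----------
    model : {"A", "B"}
        Adhesion model: A is linear in ``n``, B geometric.
    alpha : float
        Adhesion (``alpha > 0``) / repulsion (``alpha < 0``) parameter; must lie
        in ``admissible_alpha_range(model)``.
    n : int
        Number of occupied nearest-neighbour sites, 0..4.
    """
    _check_model(model)
    if not (isinstance(n, (int, np.integer)) and 0 <= n <= 4):
        raise ValueError(f"occupied-neighbour count n must be an integer in 0..4, got {n!r}")
    lo, hi = _ALPHA_RANGE[model]
    if not (lo <= alpha <= hi):
        ineq = "(4)" if model == "A" else "(6)"
        raise ValueError(
            f"alpha={alpha} outside admissible range [{lo:.6g}, {hi:.6g}] for model "
            f"{model}; the summed-probability inequality {ineq} would be violated"
        )
    if model == "A":
        return (1.0 - n * alpha) / 4.0
    return (1.0 - alpha) ** n / 4.0


@dataclass(frozen=True)
class LatticeDomain:
    """Rectangular lattice geometry and boundary behaviour.

    ``Lx`` sites per row (columns), ``Ly`` sites per column (rows).  The row
    direction is always periodic; ``x_boundary`` selects whether agents may
    leave through the left/right edges (``"flux"``) or not (``"no_flux"``).
    ``delta`` is the physical site length in micrometres (metadata only).
    """

    Lx: int
    Ly: int
    delta: float = 26.0
    x_boundary: str = "no_flux"

    def __post_init__(self) -> None:
        if self.Lx < 2 or self.Ly < 1:
            raise ValueError(f"domain must satisfy Lx >= 2 and Ly >= 1, got {self.Lx}x{self.Ly}")
        if self.x_boundary not in ("no_flux", "flux"):
            raise ValueError(f"x_boundary must be 'no_flux' or 'flux', got {self.x_boundary!r}")

    @property
    def n_sites(self) -> int:
        return self.Lx * self.Ly


@dataclass(frozen=True)
class ModelParams:
    """Motility/adhesion parameter pair Theta = (Pm, alpha) plus model choice.

    ``Pm`` is the per-agent movement-attempt rate (min^-1); ``alpha`` the
    dimensionless adhesion parameter.
    """

    Pm: float
    alpha: float
    model: str = "A"

    def __post_init__(self) -> None:
        _check_model(self.model)
        if self.Pm < 0:
            raise ValueError(f"Pm must be non-negative, got {self.Pm}")
        lo, hi = _ALPHA_RANGE[self.model]
        if not (lo <= self.alpha <= hi):
            ineq = "(4)" if self.model == "A" else "(6)"
            raise ValueError(
                f"alpha={self.alpha} outside admissible range [{lo:.6g}, {hi:.6g}] "
                f"for model {self.model} (inequality {ineq})"
            )


class OccupancyState:
    """Lattice occupancy plus per-agent registry.

    Agents carry an id, their current (1-based) column ``i`` and row ``j``, and
    the column ``i0`` they started in (used for displacement bookkeeping).  The
    grid view is derived from the registry; exclusion (at most one agent per
    site) is validated on construction.
    """

    __slots__ = ("Lx", "Ly", "ids", "col", "row", "col0")

    def __init__(
        self,
        Lx: int,
        Ly: int,
        ids: np.ndarray,
        col: np.ndarray,
        row: np.ndarray,
        col0: np.ndarray | None = None,
        validate: bool = True,
    ) -> None:
        self.Lx = int(Lx)
        self.Ly = int(Ly)
        self.ids = np.asarray(ids, dtype=np.int64)
        self.col = np.asarray(col, dtype=np.int64)
        self.row = np.asarray(row, dtype=np.int64)
        self.col0 = self.col.copy() if col0 is None else np.asarray(col0, dtype=np.int64)
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = self.ids.size
        if not (self.col.size == self.row.size == self.col0.size == n):
            raise ValueError("agent registry arrays must have equal length")
        if n:
            if self.col.min(initial=1) < 1 or self.col.max(initial=1) > self.Lx:
                raise ValueError("agent column index outside 1..Lx")
            if self.row.min(initial=1) < 1 or self.row.max(initial=1) > self.Ly:
                raise ValueError("agent row index outside 1..Ly")
            sites = (self.col - 1) * self.Ly + (self.row - 1)
            if np.unique(sites).size != n:
                raise ValueError("exclusion violated: more than one agent on a site")
            if np.unique(self.ids).size != n:
                raise ValueError("duplicate agent ids")

    @property
    def N(self) -> int:
        """Number of agents present."""
        return int(self.ids.size)

    @property
    def grid(self) -> np.ndarray:
        """Binary occupancy matrix of shape (Ly, Lx); entry [j-1, i-1] is 1 iff site (i, j) is occupied."""
        g = np.zeros((self.Ly, self.Lx), dtype=np.uint8)
        g[self.row - 1, self.col - 1] = 1
        return g

    def column_counts(self) -> np.ndarray:
        """Number of agents in each column, shape (Lx,)."""
        return np.bincount(self.col - 1, minlength=self.Lx)

    def copy(self) -> "OccupancyState":
        return OccupancyState(
            self.Lx, self.Ly, self.ids.copy(), self.col.copy(), self.row.copy(),
            self.col0.copy(), validate=False,
        )

    @classmethod
    def from_grid(cls, grid: np.ndarray, col0: np.ndarray | None = None) -> "OccupancyState":
        """Build a state from a binary (Ly, Lx) occupancy matrix; ids assigned in site order."""
        grid = np.asarray(grid)
        if grid.ndim != 2:
            raise ValueError("occupancy grid must be 2-D (Ly rows x Lx columns)")
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("occupancy grid entries must be 0 or 1")
        rows, cols = np.nonzero(grid)
        ids = np.arange(rows.size, dtype=np.int64)
        return cls(grid.shape[1], grid.shape[0], ids, cols + 1, rows + 1, col0=col0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OccupancyState):
            return NotImplemented
        if (self.Lx, self.Ly, self.N) != (other.Lx, other.Ly, other.N):
            return False
        a = np.lexsort((self.row, self.col, self.ids))
        b = np.lexsort((other.row, other.col, other.ids))
        return (
            bool(np.array_equal(self.ids[a], other.ids[b]))
            and bool(np.array_equal(self.col[a], other.col[b]))
            and bool(np.array_equal(self.row[a], other.row[b]))
            and bool(np.array_equal(self.col0[a], other.col0[b]))
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"OccupancyState({self.Lx}x{self.Ly}, N={self.N})"


def initialize_unrealistic(Lx: int = 100, Ly: int = 100) -> OccupancyState:
    """Deterministic double-sided wound: columns 1-10 and Lx-9..Lx fully occupied.

    The two 10-column occupied blocks flank an empty central region (the
    "wound") that agents migrate into.  Requires ``Lx >= 20``.
    """
    if Lx < 20:
        raise ValueError(f"Lx must be at least 20 to fit two 10-column occupied blocks, got {Lx}")
    grid = np.zeros((Ly, Lx), dtype=np.uint8)
    grid[:, :10] = 1
    grid[:, Lx - 10:] = 1
    return OccupancyState.from_grid(grid)


def initialize_from_column_densities(
    column_densities: Sequence[float], Ly: int, seed: int
) -> OccupancyState:
    """Random single-sided initial condition matching per-column densities.

    Column ``i`` receives ``round(density_i * Ly)`` agents placed uniformly at
    random without replacement among its ``Ly`` sites.  Reproducible given
    ``seed``.
    """
    dens = np.asarray(column_densities, dtype=float)
    if dens.ndim != 1 or dens.size < 2:
        raise ValueError("column_densities must be a 1-D vector of length Lx >= 2")
    if ((dens < 0) | (dens > 1)).any():
        raise ValueError("column densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    Lx = dens.size
    counts = np.floor(dens * Ly + 0.5).astype(np.int64)  # round half up
    cols, rows = [], []
    for i, c in enumerate(counts):
        if c:
            rows.append(rng.choice(Ly, size=c, replace=False) + 1)
            cols.append(np.full(c, i + 1, dtype=np.int64))
    if cols:
        col = np.concatenate(cols)
        row = np.concatenate(rows)
    else:
        col = np.empty(0, dtype=np.int64)
        row = np.empty(0, dtype=np.int64)
    ids = np.arange(col.size, dtype=np.int64)
    return OccupancyState(Lx, Ly, ids, col, row)


def replenish_left_column(
    state: OccupancyState, target_density: float, rng: np.random.Generator
) -> OccupancyState:
    """Top up column 1 to at least ``target_density`` with fresh agents.

    Mirrors the in-simulation replenishment rule of the flux-boundary design:
    agents are added to empty column-1 sites chosen uniformly at random until
    the column holds at least ``ceil(target_density * Ly)`` agents.  New agents
    get fresh ids with ``i0 = 1``.  A sufficiently full column is a no-op.
    """
    if not (0.0 <= target_density <= 1.0):
        raise ValueError(f"target_density must lie in [0, 1], got {target_density}")
    target = int(np.ceil(target_density * state.Ly - 1e-12))
    occ_rows = state.row[state.col == 1]
    deficit = target - occ_rows.size
    if deficit <= 0:
        return state.copy()
    empty_rows = np.setdiff1d(np.arange(1, state.Ly + 1), occ_rows)
    new_rows = rng.choice(empty_rows, size=deficit, replace=False)
    next_id = state.ids.max() + 1 if state.N else 0
    new_ids = np.arange(next_id, next_id + deficit, dtype=np.int64)
    return OccupancyState(
        state.Lx,
        state.Ly,
        np.concatenate([state.ids, new_ids]),
        np.concatenate([state.col, np.ones(deficit, dtype=np.int64)]),
        np.concatenate([state.row, new_rows.astype(np.int64)]),
        np.concatenate([state.col0, np.ones(deficit, dtype=np.int64)]),
    )
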