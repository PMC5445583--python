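"""Summary statistics for occupancy states and replicate ensembles.

Three statistics summarise a wound-healing simulation:

* **average horizontal displacement** -- mean over agents of the absolute
  column shift between two times (lattice-site units); adhesion decreases it,
  repulsion increases it;
* **density profile** ``C_t(i)`` -- fraction of occupied sites per column;
* **pair-correlation function (PCF)** ``q_t(m)`` -- observed horizontal
  pair counts at separation ``m = 1..Lx-1`` divided by their expectation under
  a uniformly random (volume-excluding) placement of the same number of
  agents, so ``q = 1`` signals no horizontal structure.

Pair distances never wrap the x-boundary and same-column pairs (m = 0) are
excluded from the PCF but exposed via :func:`same_column_pairs`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gillespie import SimulationRecord
from .lattice import OccupancyState

__all__ = [
    "STATISTICS",
    "StatisticVector",
    "average_horizontal_displacement",
    "density_profile",
    "pair_counts",
    "same_column_pairs",
    "pcf_normalisation",
    "pcf",
    "compute_statistic",
    "ensemble_average",
    "statistic_variance",
    "SummaryDataset",
]

STATISTICS = ("displacement", "density_profile", "pcf")


@dataclass(frozen=True)
class StatisticVector:
    """One summary-statistic vector ``S(D)_{r,t}`` at a single sampling time.

    ``values`` has length 1 for displacement, Lx for the density profile and
    Lx - 1 for the PCF.
    """

    name: str
    t: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in STATISTICS:
            raise ValueError(f"unknown statistic {self.name!r}; expected one of {STATISTICS}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def average_horizontal_displacement(record: SimulationRecord, t_i: float, t_f: float) -> float:
    """Mean absolute column displacement between ``t_i`` and ``t_f``.

    Only agents present at both times contribute (agents that left through a
    flux boundary, or were added by replenishment in between, are excluded).
    """
    if not t_i < t_f:
        raise ValueError(f"need t_i < t_f, got {t_i} >= {t_f}")
    s0 = record.state_at(t_i)
    s1 = record.state_at(t_f)
    common, a0, a1 = np.intersect1d(s0.ids, s1.ids, return_indices=True)
    if common.size == 0:
        raise ValueError(f"no agent present at both t={t_i} and t={t_f}")
    return float(np.mean(np.abs(s0.col[a0] - s1.col[a1])))


def density_profile(state: OccupancyState) -> np.ndarray:
    """Per-column occupied fraction ``C_t(i)``, shape (Lx,), values in [0, 1]."""
    return state.column_counts() / state.Ly


def pair_counts(state: OccupancyState) -> np.ndarray:
    """Number of unordered agent pairs at each horizontal separation m = 1..Lx-1.

    Distances are measured along columns only and never wrap the x-boundary.
    """
    h = state.column_counts().astype(np.int64)
    full = np.correlate(h, h, mode="full")  # full[Lx-1+m] = sum_i h_i h_{i+m}
    return full[state.Lx:].astype(np.int64)


def same_column_pairs(state: OccupancyState) -> int:
    """Number of unordered agent pairs sharing a column (the excluded m = 0 term)."""
    h = state.column_counts().astype(np.int64)
    return int((h * (h - 1) // 2).sum())


def pcf_normalisation(Lx: int, Ly: int, N: int) -> np.ndarray:
    """Expected pair counts ``c_hat(m) = Ly^2 (Lx - m) rho rho_hat`` under random placement.

    ``rho = N / (Lx Ly)`` and ``rho_hat = (N - 1) / (Lx Ly - 1)`` account for
    volume exclusion (an agent cannot pair with itself).  Requires ``N >= 2``.
    """
    if N < 2:
        raise ValueError(f"PCF normalisation requires at least 2 agents, got N={N}")
    m = np.arange(1, Lx)
    rho = N / (Lx * Ly)
    rho_hat = (N - 1) / (Lx * Ly - 1)
    return Ly**2 * (Lx - m) * rho * rho_hat


def pcf(state: OccupancyState) -> np.ndarray:
    """Pair-correlation function ``q_t(m) = c_t(m) / c_hat(m)``, m = 1..Lx-1."""
    return pair_counts(state) / pcf_normalisation(state.Lx, state.Ly, state.N)


def compute_statistic(name: str, record: SimulationRecord, t: float, t_i: float = 0.0) -> StatisticVector:
    """Evaluate one named statistic on a recorded snapshot.

    Displacement is measured over ``[t_i, t]`` (default from the start of the
    simulation); the other statistics depend only on the state at ``t``.
    """
    if name == "displacement":
        values = np.array([average_horizontal_displacement(record, t_i, t)])
    elif name == "density_profile":
        values = density_profile(record.state_at(t))
    elif name == "pcf":
        values = pcf(record.state_at(t))
    else:
        raise ValueError(f"unknown statistic {name!r}; expected one of {STATISTICS}")
    return StatisticVector(name, float(t), values)


def _check_homogeneous(stats: Sequence[StatisticVector]) -> np.ndarray:
    if not stats:
        raise ValueError("empty replicate list")
    first = stats[0]
    for s in stats[1:]:
        if s.name != first.name or s.t != first.t or s.values.shape != first.values.shape:
            raise ValueError(
                f"mixed statistics: ({s.name}, t={s.t}, len={s.values.size}) vs "
                f"({first.name}, t={first.t}, len={first.values.size})"
            )
    return np.vstack([s.values for s in stats])


def ensemble_average(stats: Sequence[StatisticVector]) -> StatisticVector:
    """Elementwise mean over replicate statistic vectors of one kind and time."""
    mat = _check_homogeneous(stats)
    return StatisticVector(stats[0].name, stats[0].t, mat.mean(axis=0))


def statistic_variance(stats: Sequence[StatisticVector]) -> np.ndarray:
    """Elementwise unbiased sample variance over replicates (needs >= 2 replicates)."""
    mat = _check_homogeneous(stats)
    if mat.shape[0] < 2:
        raise ValueError("variance is undefined for a single replicate")
    return mat.var(axis=0, ddof=1)


class SummaryDataset:
    """Per-replicate summary statistics and their ensemble averages.

    Stores, for each (statistic, time) pair, an ``(n_replicates, R)`` matrix of
    replicate statistic vectors.  The ensemble average is the elementwise mean
    over replicates; the observed side of an ABC comparison always enters
    through these averages.
    """

    def __init__(
        self,
        statistics: Sequence[str],
        times: Sequence[float],
        data: dict[tuple[str, float], np.ndarray],
        meta: dict | None = None,
    ) -> None:
        self.statistics = tuple(statistics)
        self.times = tuple(float(t) for t in times)
        self.meta = dict(meta or {})
        self._data: dict[tuple[str, float], np.ndarray] = {}
        n_reps = None
        for name in self.statistics:
            if name not in STATISTICS:
                raise ValueError(f"unknown statistic {name!r}")
            for t in self.times:
                mat = np.asarray(data[(name, t)], dtype=float)
                if mat.ndim != 2:
                    raise ValueError(f"replicate matrix for ({name}, {t}) must be 2-D")
                if n_reps is None:
                    n_reps = mat.shape[0]
                elif mat.shape[0] != n_reps:
                    raise ValueError("inconsistent replicate counts across statistics")
                self._data[(name, t)] = mat
        self.n_replicates = int(n_reps or 0)

    @classmethod
    def from_replicates(
        cls,
        replicate_stats: Sequence[Sequence[StatisticVector]],
        meta: dict | None = None,
    ) -> "SummaryDataset":
        """Assemble a dataset from one list of StatisticVectors per replicate."""
        if not replicate_stats:
            raise ValueError("no replicates supplied")
        keys = [(s.name, s.t) for s in replicate_stats[0]]
        names = tuple(dict.fromkeys(k[0] for k in keys))
        times = tuple(dict.fromkeys(k[1] for k in keys))
        data: dict[tuple[str, float], np.ndarray] = {}
        for name, t in keys:
            rows = []
            for rep in replicate_stats:
                match = [s for s in rep if s.name == name and s.t == t]
                if len(match) != 1:
                    raise ValueError(f"replicate missing statistic ({name}, t={t})")
                rows.append(match[0].values)
            data[(name, t)] = np.vstack(rows)
        return cls(names, times, data, meta)

    def replicates(self, name: str, t: float) -> np.ndarray:
        """The ``(n_replicates, R)`` matrix for one statistic/time."""
        return self._data[(name, float(t))]

    def mean(self, name: str, t: float) -> np.ndarray:
        """Ensemble average over replicates for one statistic/time."""
        return self._data[(name, float(t))].mean(axis=0)

    def variance(self, name: str, t: float) -> np.ndarray:
        """Unbiased elementwise variance over replicates for one statistic/time."""
        mat = self._data[(name, float(t))]
        if mat.shape[0] < 2:
            raise ValueError("variance is undefined for a single replicate")
        return mat.var(axis=0, ddof=1)

    def items(self):
        return self._data.items()
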