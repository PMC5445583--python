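"""Exact continuous-time simulation of the adhesive exclusion process.

Each agent carries a movement-attempt rate ``Pm``; the waiting time between
attempts in a population of ``N`` agents is exponential with rate ``N * Pm``
and the attempting agent is chosen uniformly (Gillespie direct method with a
homogeneous rate).  A selected agent with ``n`` occupied nearest neighbours
moves to each *available* target -- an empty in-domain neighbour, or the
off-domain exit direction at a flux boundary -- with probability ``T(n)``
given by the adhesion model, and otherwise stays put.  Attempts that fail
still consume the event.  The admissibility bounds on ``alpha`` guarantee the
summed success probability never exceeds one.

Boundary handling: rows wrap periodically (a 1-row lattice has no vertical
neighbours; self-loops are excluded), columns never wrap.  Under ``no_flux``
x-boundaries the edge directions are simply unavailable; under ``flux``
boundaries an agent selecting an off-domain direction leaves the simulation.
The realistic wound-assay design additionally keeps the left-most column at or
above a target density: whenever a movement event vacates a column-1 site,
agents are added to empty column-1 sites uniformly at random until the target
count is restored.

Two compiled kernels share the event logic: a fixed-population kernel for
closed domains (no flux, no replenishment), where the constant total rate lets
event counts per sampling interval be drawn as Poisson variates with no
per-event clock, and an open-population kernel that tracks exponential waiting
times and an explicit alive-agent registry.  Both are distributionally exact
realisations of the same Markov process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .lattice import LatticeDomain, ModelParams, OccupancyState

__all__ = ["SimulationRecord", "gillespie_run"]

_OVERFLOW = 1


@njit(cache=True, fastmath=True)
def _run_fixed(Lx, Ly, pm, alpha, model_is_a, col, row, n0, times, seed,
               snap_col, snap_row):
    """Closed-domain kernel: constant population, Poisson event counts per interval."""
    np.random.seed(seed)
    grid = np.full((Ly, Lx), -1, dtype=np.int64)
    for a in range(n0):
        grid[row[a], col[a]] = a
    tgt_c = np.empty(4, dtype=np.int64)
    tgt_r = np.empty(4, dtype=np.int64)
    t_prev = 0.0
    for k in range(times.shape[0]):
        lam = n0 * pm * (times[k] - t_prev)
        t_prev = times[k]
        n_events = np.random.poisson(lam) if lam > 0.0 else 0
        for _ in range(n_events):
            a = int(np.random.random() * n0)
            ci = col[a]
            ri = row[a]
            # neighbour scan: count occupied, collect empty targets
            n_occ = 0
            n_tgt = 0
            nc = ci - 1
            if nc >= 0:
                if grid[ri, nc] >= 0:
                    n_occ += 1
                else:
                    tgt_c[n_tgt] = nc
                    tgt_r[n_tgt] = ri
                    n_tgt += 1
            nc = ci + 1
            if nc < Lx:
                if grid[ri, nc] >= 0:
                    n_occ += 1
                else:
                    tgt_c[n_tgt] = nc
                    tgt_r[n_tgt] = ri
                    n_tgt += 1
            if Ly > 1:  # periodic rows; a 1-row lattice has no vertical neighbours
                nr = ri - 1
                if nr < 0:
                    nr = Ly - 1
                if grid[nr, ci] >= 0:
                    n_occ += 1
                else:
                    tgt_c[n_tgt] = ci
                    tgt_r[n_tgt] = nr
                    n_tgt += 1
                nr = ri + 1
                if nr >= Ly:
                    nr = 0
                if grid[nr, ci] >= 0:
                    n_occ += 1
                else:
                    tgt_c[n_tgt] = ci
                    tgt_r[n_tgt] = nr
                    n_tgt += 1
            if n_tgt == 0:
                continue
            if model_is_a:
                T = (1.0 - n_occ * alpha) / 4.0
            else:
                T = (1.0 - alpha) ** n_occ / 4.0
            r = np.random.random()
            if r >= n_tgt * T:
                continue  # no-move outcome; the attempt still consumed the event
            j = int(r / T)
            if j >= n_tgt:
                j = n_tgt - 1
            tc = tgt_c[j]
            tr = tgt_r[j]
            grid[ri, ci] = -1
            grid[tr, tc] = a
            col[a] = tc
            row[a] = tr
        for a in range(n0):
            snap_col[k, a] = col[a]
            snap_row[k, a] = row[a]
    return 0


@njit(cache=True, fastmath=True)
def _run_open(Lx, Ly, pm, alpha, model_is_a, x_flux, replenish, target_count,
              col, row, col0, n0, cap, times, seed,
              snap_col, snap_row, snap_col0, snap_alive, snap_n):
    """Open-domain kernel: flux exits and/or left-column replenishment."""
    np.random.seed(seed)
    grid = np.full((Ly, Lx), -1, dtype=np.int64)
    alive = np.zeros(cap, dtype=np.uint8)
    active = np.empty(cap, dtype=np.int64)
    apos = np.full(cap, -1, dtype=np.int64)
    for a in range(n0):
        grid[row[a], col[a]] = a
        active[a] = a
        apos[a] = a
        alive[a] = 1
    n_alive = n0
    n_agents = n0
    n_times = times.shape[0]
    tgt_c = np.empty(4, dtype=np.int64)
    tgt_r = np.empty(4, dtype=np.int64)
    empty_rows = np.empty(Ly, dtype=np.int64)

    t = 0.0
    k = 0
    while k < n_times:
        total = n_alive * pm
        if total <= 0.0:
            # no further events can ever occur (fastmath forbids an inf clock)
            while k < n_times:
                for a in range(n_agents):
                    snap_col[k, a] = col[a]
                    snap_row[k, a] = row[a]
                    snap_col0[k, a] = col0[a]
                    snap_alive[k, a] = alive[a]
                snap_n[k] = n_agents
                k += 1
            break
        dt = np.random.exponential(1.0 / total)
        while k < n_times and t + dt > times[k]:
            for a in range(n_agents):
                snap_col[k, a] = col[a]
                snap_row[k, a] = row[a]
                snap_col0[k, a] = col0[a]
                snap_alive[k, a] = alive[a]
            snap_n[k] = n_agents
            k += 1
        if k >= n_times:
            break
        t += dt

        a = active[int(np.random.random() * n_alive)]
        ci = col[a]
        ri = row[a]
        # neighbour scan: count occupied, collect targets (flux exits marked -1)
        n_occ = 0
        n_tgt = 0
        nc = ci - 1
        if nc >= 0:
            if grid[ri, nc] >= 0:
                n_occ += 1
            else:
                tgt_c[n_tgt] = nc
                tgt_r[n_tgt] = ri
                n_tgt += 1
        elif x_flux:
            tgt_c[n_tgt] = -1
            n_tgt += 1
        nc = ci + 1
        if nc < Lx:
            if grid[ri, nc] >= 0:
                n_occ += 1
            else:
                tgt_c[n_tgt] = nc
                tgt_r[n_tgt] = ri
                n_tgt += 1
        elif x_flux:
            tgt_c[n_tgt] = -1
            n_tgt += 1
        if Ly > 1:  # periodic rows; a 1-row lattice has no vertical neighbours
            nr = ri - 1
            if nr < 0:
                nr = Ly - 1
            if grid[nr, ci] >= 0:
                n_occ += 1
            else:
                tgt_c[n_tgt] = ci
                tgt_r[n_tgt] = nr
                n_tgt += 1
            nr = ri + 1
            if nr >= Ly:
                nr = 0
            if grid[nr, ci] >= 0:
                n_occ += 1
            else:
                tgt_c[n_tgt] = ci
                tgt_r[n_tgt] = nr
                n_tgt += 1
        if n_tgt == 0:
            continue
        if model_is_a:
            T = (1.0 - n_occ * alpha) / 4.0
        else:
            T = (1.0 - alpha) ** n_occ / 4.0
        r = np.random.random()
        if r >= n_tgt * T:
            continue
        j = int(r / T)
        if j >= n_tgt:
            j = n_tgt - 1
        tc = tgt_c[j]

        vacated_left = ci == 0
        if tc < 0:
            # flux exit: the agent leaves the domain
            grid[ri, ci] = -1
            alive[a] = 0
            p = apos[a]
            last = active[n_alive - 1]
            active[p] = last
            apos[last] = p
            apos[a] = -1
            n_alive -= 1
        else:
            tr = tgt_r[j]
            grid[ri, ci] = -1
            grid[tr, tc] = a
            col[a] = tc
            row[a] = tr
            if tc == 0:
                vacated_left = False  # vertical move inside column 1

        if replenish and vacated_left:
            count = 0
            for rr in range(Ly):
                if grid[rr, 0] >= 0:
                    count += 1
            while count < target_count:
                n_empty = 0
                for rr in range(Ly):
                    if grid[rr, 0] < 0:
                        empty_rows[n_empty] = rr
                        n_empty += 1
                pick = empty_rows[int(np.random.random() * n_empty)]
                if n_agents >= cap:
                    return _OVERFLOW
                b = n_agents
                n_agents += 1
                col[b] = 0
                row[b] = pick
                col0[b] = 0
                alive[b] = 1
                grid[pick, 0] = b
                active[n_alive] = b
                apos[b] = n_alive
                n_alive += 1
                count += 1
    return 0


@dataclass
class SimulationRecord:
    """Snapshots of one simulation at the requested sampling times.

    ``snapshots`` maps each requested time (min) to a copy of the occupancy
    state; ``initial`` is the state at t = 0 regardless of whether 0 was
    requested.  Agent ids are stable across snapshots, so displacement can be
    computed for agents present at two times.
    """

    domain: LatticeDomain
    params: ModelParams
    times: tuple[float, ...]
    snapshots: Mapping[float, OccupancyState]
    initial: OccupancyState
    seed: int
    meta: dict = field(default_factory=dict)

    def state_at(self, t: float) -> OccupancyState:
        """Snapshot at time ``t``; ``t = 0`` returns the initial state."""
        if t in self.snapshots:
            return self.snapshots[t]
        if t == 0:
            return self.initial
        raise KeyError(f"time {t} was not recorded (times: {self.times})")


def gillespie_run(
    domain: LatticeDomain,
    params: ModelParams,
    initial: OccupancyState,
    times: Sequence[float],
    seed: int,
    replenish_density: float | None = None,
) -> SimulationRecord:
    """Simulate the exclusion process and record snapshots at ``times``.

    Parameters
    ----------
    domain, params
        Lattice geometry / boundary behaviour and Theta = (Pm, alpha, model).
    initial
        Starting occupancy state (must satisfy exclusion; validated).
    times
        Strictly ascending sampling times (minutes).
    seed
        Seed for the simulation RNG; runs are bit-reproducible given the seed.
    replenish_density
        If not None, keep column 1 at or above this density: after any
        movement event that vacates a column-1 site, empty column-1 sites are
        filled uniformly at random up to ``ceil(density * Ly)`` agents.
    """
    if (initial.Lx, initial.Ly) != (domain.Lx, domain.Ly):
        raise ValueError("initial state does not match the domain dimensions")
    initial._validate()
    times_arr = np.asarray(times, dtype=float)
    if times_arr.ndim != 1:
        raise ValueError("times must be a 1-D sequence")
    if times_arr.size and (np.diff(times_arr) <= 0).any():
        raise ValueError("times must be strictly ascending")
    if (times_arr < 0).any():
        raise ValueError("times must be non-negative")
    replenish = replenish_density is not None
    if replenish and not (0.0 <= replenish_density <= 1.0):
        raise ValueError("replenish_density must lie in [0, 1]")
    target_count = int(np.ceil(replenish_density * domain.Ly - 1e-12)) if replenish else 0

    n0 = initial.N
    n_times = times_arr.size
    seed32 = int(seed) % (2**31)
    open_domain = domain.x_boundary == "flux" or replenish

    if n0 == 0 and not replenish:
        empty = initial.copy()
        snaps = {float(t): empty.copy() for t in times_arr}
        return SimulationRecord(domain, params, tuple(times_arr), snaps, empty, int(seed))

    if not open_domain:
        col = (initial.col - 1).astype(np.int64)
        row = (initial.row - 1).astype(np.int64)
        snap_col = np.zeros((n_times, n0), dtype=np.int64)
        snap_row = np.zeros((n_times, n0), dtype=np.int64)
        _run_fixed(domain.Lx, domain.Ly, float(params.Pm), float(params.alpha),
                   params.model == "A", col, row, n0, times_arr, seed32,
                   snap_col, snap_row)
        snaps = {
            float(t): OccupancyState(
                domain.Lx, domain.Ly, initial.ids.copy(),
                snap_col[k] + 1, snap_row[k] + 1, initial.col0.copy(),
            )
            for k, t in enumerate(times_arr)
        }
        return SimulationRecord(
            domain, params, tuple(float(t) for t in times_arr), snaps,
            initial.copy(), int(seed),
        )

    horizon = float(times_arr[-1]) if n_times else 0.0
    extra = int(4 * domain.Ly * max(params.Pm, 1e-9) * horizon) + domain.Ly + 16 if replenish else 0
    while True:
        cap = n0 + extra
        col = np.zeros(cap, dtype=np.int64)
        row = np.zeros(cap, dtype=np.int64)
        col0 = np.zeros(cap, dtype=np.int64)
        col[:n0] = initial.col - 1
        row[:n0] = initial.row - 1
        col0[:n0] = initial.col0 - 1
        snap_col = np.zeros((n_times, cap), dtype=np.int64)
        snap_row = np.zeros((n_times, cap), dtype=np.int64)
        snap_col0 = np.zeros((n_times, cap), dtype=np.int64)
        snap_alive = np.zeros((n_times, cap), dtype=np.uint8)
        snap_n = np.zeros(n_times, dtype=np.int64)
        status = _run_open(
            domain.Lx, domain.Ly, float(params.Pm), float(params.alpha),
            params.model == "A", domain.x_boundary == "flux", replenish,
            target_count, col, row, col0, n0, cap, times_arr, seed32,
            snap_col, snap_row, snap_col0, snap_alive, snap_n,
        )
        if status == 0:
            break
        extra = max(2 * extra, 64)  # deterministic retry with a larger registry

    # Kernel agent index == registry slot; initial agents keep their input ids,
    # agents created by replenishment get fresh consecutive ids.
    id_map = np.zeros(cap, dtype=np.int64)
    id_map[:n0] = initial.ids
    if cap > n0:
        next_id = initial.ids.max() + 1 if n0 else 0
        id_map[n0:] = np.arange(next_id, next_id + cap - n0)

    snaps = {}
    for k, t in enumerate(times_arr):
        m = snap_n[k]
        live = snap_alive[k, :m].astype(bool)
        snaps[float(t)] = OccupancyState(
            domain.Lx, domain.Ly,
            id_map[:m][live],
            snap_col[k, :m][live] + 1,
            snap_row[k, :m][live] + 1,
            snap_col0[k, :m][live] + 1,
        )
    return SimulationRecord(
        domain, params, tuple(float(t) for t in times_arr), snaps, initial.copy(), int(seed)
    )
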