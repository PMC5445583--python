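"""Text serialisation: occupancy CSVs, dataset tables, posterior tables, provenance.

Everything is plain CSV + JSON so runs are portable and diffable.  Floats are
written with 17 significant digits, which round-trips IEEE doubles exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .abc import PosteriorResult
from .lattice import LatticeDomain, OccupancyState
from .summaries import SummaryDataset

__all__ = [
    "write_occupancy_csv",
    "read_occupancy_csv",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_posterior_csv",
    "read_posterior_csv",
    "write_provenance",
]

_FLOAT_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_occupancy_csv(state: OccupancyState, path: str | Path,
                        domain: LatticeDomain | None = None) -> None:
    """Write a state as a Ly x Lx matrix of 0/1 (row 1 = j = 1) plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, state.grid, fmt="%d", delimiter=",")
    meta = {"Lx": state.Lx, "Ly": state.Ly}
    if domain is not None:
        meta.update({"delta": domain.delta, "x_boundary": domain.x_boundary,
                     "y_boundary": "periodic"})
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_occupancy_csv(path: str | Path) -> OccupancyState:
    """Read an occupancy matrix written by :func:`write_occupancy_csv` (or user-supplied)."""
    grid = np.loadtxt(Path(path), delimiter=",", dtype=np.int64, ndmin=2)
    return OccupancyState.from_grid(grid)


def write_dataset_csv(dataset: SummaryDataset, path: str | Path) -> None:
    """Long-format dataset table (statistic, t, replicate, index r, value) + meta JSON."""
    path = Path(path)
    rows = []
    for (name, t), mat in dataset.items():
        for rep in range(mat.shape[0]):
            for r in range(mat.shape[1]):
                rows.append((name, t, rep + 1, r + 1, mat[rep, r]))
    df = pd.DataFrame(rows, columns=["statistic", "t", "replicate", "r", "value"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    _sidecar(path).write_text(json.dumps(dataset.meta, indent=2, default=_jsonable))


def read_dataset_csv(path: str | Path) -> SummaryDataset:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    names = tuple(dict.fromkeys(df["statistic"]))
    times = tuple(dict.fromkeys(df["t"]))
    data = {}
    for name in names:
        for t in times:
            sub = df[(df["statistic"] == name) & (df["t"] == t)]
            mat = sub.pivot(index="replicate", columns="r", values="value").sort_index()
            data[(name, float(t))] = mat.to_numpy()
    return SummaryDataset(names, times, data, meta)


def write_posterior_csv(result: PosteriorResult, path: str | Path) -> None:
    """Posterior samples/chain as CSV (index, Pm, alpha, d, accepted) + run-metadata JSON."""
    path = Path(path)
    accepted = (result.accepted if result.accepted is not None
                else np.ones(len(result.samples), dtype=bool))
    df = pd.DataFrame({
        "index": np.arange(len(result.samples)),
        "Pm": result.samples[:, 0],
        "alpha": result.samples[:, 1],
        "d": result.distances,
        "accepted": accepted.astype(int),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "method": result.method,
        "seed": result.seed,
        "epsilon": result.epsilon,
        "prior": {"pm_bounds": list(result.prior.pm_bounds),
                  "alpha_bounds": list(result.prior.alpha_bounds),
                  "model": result.prior.model},
        "spec": {"statistics": list(result.spec.statistics),
                 "times": list(result.spec.times),
                 "weights": dict(result.spec.weights)},
        **result.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=_jsonable))


def read_posterior_csv(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Return (samples (n, 2), full table, metadata) from a posterior CSV."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return df[["Pm", "alpha"]].to_numpy(), df, meta


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_provenance(path: str | Path, **record) -> None:
    """Write a JSON provenance record (design, params, seeds, settings) for a run."""
    Path(path).write_text(json.dumps(record, indent=2, default=_jsonable, sort_keys=True))
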