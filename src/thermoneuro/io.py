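"""Plain-text serialization: TSV tables with JSON sidecars where needed.

Spike rasters are stored as (neuron_id, bin_index) event lists with a JSON
header carrying the time grid; lag functions as two-column TSV
(lag_ms, value); matrices and graph edge lists as TSV.  All writers emit a
one-line ``#`` comment naming the quantity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import LagFunction, SpikeRaster, TimeGrid

__all__ = [
    "write_raster",
    "read_raster",
    "write_lag_function",
    "read_lag_function",
    "write_matrix",
    "read_matrix",
    "write_edge_list",
    "write_json",
]


def write_raster(prefix: str | Path, raster: SpikeRaster, comment: str = "spike raster") -> None:
    prefix = Path(prefix)
    neuron, bins = np.nonzero(raster.values)
    with open(prefix.with_suffix(".tsv"), "w") as fh:
        fh.write(f"# {comment}: event list\n")
        fh.write("neuron_id\tbin_index\n")
        for i, b in zip(neuron, bins):
            fh.write(f"{i}\t{b}\n")
    header = {
        "dt": raster.grid.dt,
        "n_steps": raster.grid.n_steps,
        "n_neurons": raster.n_neurons,
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_raster(prefix: str | Path) -> SpikeRaster:
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    grid = TimeGrid(dt=header["dt"], n_steps=header["n_steps"])
    values = np.zeros((header["n_neurons"], grid.n_steps), dtype=np.int8)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", comment="#")
    if len(df):
        values[df["neuron_id"].to_numpy(), df["bin_index"].to_numpy()] = 1
    return SpikeRaster(values, grid)


def write_lag_function(path: str | Path, lf: LagFunction, comment: str = "lag function") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write("lag_ms\tvalue\n")
        for l, v in zip(lf.lags, lf.values):
            fh.write(f"{l:.6g}\t{v:.10g}\n")


def read_lag_function(path: str | Path) -> LagFunction:
    df = pd.read_csv(path, sep="\t", comment="#")
    return LagFunction(df["lag_ms"].to_numpy(float), df["value"].to_numpy(float))


def write_matrix(path: str | Path, M: np.ndarray, comment: str = "matrix") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        np.savetxt(fh, np.asarray(M), delimiter="\t", fmt="%.10g")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", comments="#")


def write_edge_list(path: str | Path, adjacency: np.ndarray, comment: str = "graph edge list") -> None:
    A = np.asarray(adjacency)
    rows, cols = np.nonzero(np.triu(A, k=1))
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write("node_i\tnode_j\n")
        for i, j in zip(rows, cols):
            fh.write(f"{i}\t{j}\n")


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_np_default))


def _np_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
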