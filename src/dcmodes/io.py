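"""Plain-text file formats.

Timeseries and stimulus functions are delimiter-separated text with a
header row; acquisition metadata (TR, microtime step) lives in a JSON
sidecar next to the data file (``<name>.json``).
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from .model_core import InputFunctions, TimeSeries


def _sidecar(path) -> pathlib.Path:
    p = pathlib.Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_timeseries(ts: TimeSeries, path, sep: str = "\t") -> None:
    labels = ts.node_labels or [f"node{i + 1}" for i in range(ts.n_nodes)]
    pd.DataFrame(ts.Y, columns=list(labels)).to_csv(path, sep=sep,
                                                    index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump({"TR": ts.TR, "n_volumes": ts.n_volumes}, fh)


def read_timeseries(path, sep: str = "\t",
                    TR: float | None = None) -> TimeSeries:
    df = pd.read_csv(path, sep=sep)
    if TR is None:
        with open(_sidecar(path)) as fh:
            TR = json.load(fh)["TR"]
    return TimeSeries(Y=df.to_numpy(float), TR=float(TR),
                      node_labels=tuple(df.columns))


def write_inputs(u: InputFunctions, path, sep: str = "\t") -> None:
    cols = [f"input{i + 1}" for i in range(u.n_inputs)]
    pd.DataFrame(u.u, columns=cols).to_csv(path, sep=sep, index=False)
    with open(_sidecar(path), "w") as fh:
        json.dump({"dt_micro": u.dt_micro, "TR": u.TR,
                   "n_volumes": u.n_volumes}, fh)


def read_inputs(path, sep: str = "\t") -> InputFunctions:
    df = pd.read_csv(path, sep=sep)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    return InputFunctions(u=df.to_numpy(float), dt_micro=meta["dt_micro"],
                          TR=meta["TR"], n_volumes=meta["n_volumes"])
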