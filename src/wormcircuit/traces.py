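"""Neuron-by-time voltage trajectories and their on-disk dialects.

A :class:`TraceSet` holds a uniform time grid plus an N x T voltage matrix
(one row per neuron, matrix order = connectome order) and optionally the
synaptic activation matrix.  Writers/readers cover a wide CSV (first column
``time_s``, one column per neuron) and a compact HDF5 layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["TraceSet", "write_traces_csv", "read_traces_csv",
           "write_traces_hdf5", "read_traces_hdf5"]


@dataclass
class TraceSet:
    time: np.ndarray                      # (T,) s, uniform step
    voltage: np.ndarray                   # (N, T) mV
    names: list[str]
    activation: np.ndarray | None = None  # (N, T) in [0, 1]
    protocol_id: str = ""
    params_fingerprint: str = ""
    ablated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ValueError("time must be a vector of >= 2 samples")
        steps = np.diff(self.time)
        if (steps <= 0).any() or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("time must be strictly increasing and uniform")
        if self.voltage.shape != (len(self.names), len(self.time)):
            raise ValueError(
                f"voltage shape {self.voltage.shape} != "
                f"({len(self.names)}, {len(self.time)})"
            )
        if self.activation is not None:
            self.activation = np.asarray(self.activation, dtype=float)
            if self.activation.shape != self.voltage.shape:
                raise ValueError("activation shape mismatch")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def trace(self, name: str) -> np.ndarray:
        return self.voltage[self.names.index(name)]

    def subset(self, names: list[str]) -> "TraceSet":
        idx = [self.names.index(nm) for nm in names]
        return TraceSet(
            time=self.time,
            voltage=self.voltage[idx],
            names=list(names),
            activation=None if self.activation is None else self.activation[idx],
            protocol_id=self.protocol_id,
            params_fingerprint=self.params_fingerprint,
            ablated=self.ablated,
        )


def write_traces_csv(traces: TraceSet, path: str | Path) -> None:
    """Wide CSV: time_s column then one voltage column per neuron.

    Metadata (protocol, fingerprint, ablations) is stored in ``#``-prefixed
    header comment lines so the file stays a single self-describing artifact.
    """
    meta = {
        "protocol_id": traces.protocol_id,
        "params_fingerprint": traces.params_fingerprint,
        "ablated": list(traces.ablated),
    }
    df = pd.DataFrame(traces.voltage.T, columns=traces.names)
    df.insert(0, "time_s", traces.time)
    with open(path, "w") as fh:
        fh.write(f"# wormcircuit-traces {json.dumps(meta)}\n")
        df.to_csv(fh, index=False)


def read_traces_csv(path: str | Path) -> TraceSet:
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# wormcircuit-traces"):
            meta = json.loads(first.split(None, 2)[2])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    names = [c for c in df.columns if c != "time_s"]
    return TraceSet(
        time=df["time_s"].to_numpy(),
        voltage=df[names].to_numpy().T,
        names=names,
        protocol_id=meta.get("protocol_id", ""),
        params_fingerprint=meta.get("params_fingerprint", ""),
        ablated=tuple(meta.get("ablated", ())),
    )


def write_traces_hdf5(traces: TraceSet, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time", data=traces.time)
        h5.create_dataset("voltages", data=traces.voltage)
        if traces.activation is not None:
            h5.create_dataset("activations", data=traces.activation)
        h5.create_dataset(
            "names", data=np.array(traces.names, dtype=h5py.string_dtype())
        )
        h5.attrs["protocol_id"] = traces.protocol_id
        h5.attrs["params_fingerprint"] = traces.params_fingerprint
        h5.attrs["ablated"] = json.dumps(list(traces.ablated))


def read_traces_hdf5(path: str | Path) -> TraceSet:
    with h5py.File(path, "r") as h5:
        return TraceSet(
            time=h5["time"][:],
            voltage=h5["voltages"][:],
            activation=h5["activations"][:] if "activations" in h5 else None,
            names=[s.decode() for s in h5["names"][:]],
            protocol_id=h5.attrs.get("protocol_id", ""),
            params_fingerprint=h5.attrs.get("params_fingerprint", ""),
            ablated=tuple(json.loads(h5.attrs.get("ablated", "[]"))),
        )
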