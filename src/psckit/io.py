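"""File I/O: traces (HDF5/CSV), ground truth, event tables, YAML configs."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import GroundTruthEvent
from .trace import Trace

__all__ = [
    "write_traces_hdf5", "read_traces_hdf5",
    "write_trace_csv", "read_trace_csv",
    "write_ground_truth_csv", "read_ground_truth_csv",
    "load_yaml", "dump_yaml",
]


def write_traces_hdf5(path, traces: dict[str, Trace]) -> None:
    """One group per cell: dataset ``samples`` plus acquisition attributes."""
    with h5py.File(path, "w") as f:
        for cell_id, trace in traces.items():
            g = f.create_group(str(cell_id))
            g.create_dataset("samples", data=trace.samples, compression="gzip")
            g.attrs["sampling_rate"] = trace.sampling_rate
            g.attrs["condition"] = trace.condition
            g.attrs["seed"] = int(trace.meta.get("seed", -1))


def read_traces_hdf5(path) -> dict[str, Trace]:
    out = {}
    with h5py.File(path, "r") as f:
        for cell_id in f:
            g = f[cell_id]
            out[cell_id] = Trace(
                g["samples"][()], float(g.attrs["sampling_rate"]),
                trace_id=cell_id, condition=str(g.attrs.get("condition", "")),
                meta={"seed": int(g.attrs.get("seed", -1))})
    return out


def write_trace_csv(path, trace: Trace) -> None:
    pd.DataFrame({"time_s": trace.times(), "current_pA": trace.samples}) \
        .to_csv(path, index=False)


def read_trace_csv(path, sampling_rate: float | None = None) -> Trace:
    df = pd.read_csv(path)
    if sampling_rate is None:
        dt = np.diff(df["time_s"].to_numpy()[:2])[0]
        sampling_rate = 1.0 / dt
    return Trace(df["current_pA"].to_numpy(), sampling_rate)


def write_ground_truth_csv(path, cells: dict) -> None:
    """cells: {cell_id: {"events": [GroundTruthEvent, ...], ...}}."""
    rows = [{
        "cell_id": cell_id, "onset_s": ev.onset, "amplitude_pA": ev.amplitude,
        "population": ev.rise_population, "rise_ms": ev.rise_ms,
        "tau_rise_ms": ev.tau_rise_ms, "tau_decay_ms": ev.tau_decay_ms,
    } for cell_id, cell in cells.items() for ev in cell["events"]]
    pd.DataFrame(rows, columns=["cell_id", "onset_s", "amplitude_pA",
                                "population", "rise_ms", "tau_rise_ms",
                                "tau_decay_ms"]).to_csv(path, index=False)


def read_ground_truth_csv(path) -> dict:
    df = pd.read_csv(path, dtype={"cell_id": str})
    out: dict = {}
    for cell_id, grp in df.groupby("cell_id"):
        out[cell_id] = {"events": [
            GroundTruthEvent(r.onset_s, r.amplitude_pA, r.population,
                             r.rise_ms, r.tau_rise_ms, r.tau_decay_ms)
            for r in grp.itertuples()]}
    return out


def load_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def dump_yaml(path, data: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=True)
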