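"""Session container I/O.

A session is a hierarchical HDF5 store emulating a spike-times + tracking
deposit:

    /tracking/t, /tracking/x, /tracking/y     seconds and cm, ~120 Hz
    /units/<id>/spike_times                   seconds, per unit
    /units/<id>  attrs: module, spacing
    root attrs: arena_radius, arena_topology, dt

The same schema is the target for converted real recordings; the reader bins
spike times onto the tracking clock and applies the standard minimum-spike
inclusion criterion (500 spikes).
"""

from __future__ import annotations

import numpy as np

from .arena import Arena
from .synthetic import SpikeData, Trajectory

__all__ = ["SchemaError", "write_session", "read_session"]


class SchemaError(RuntimeError):
    """A session file does not conform to the expected layout."""


def _counts_to_spike_times(counts: np.ndarray, times: np.ndarray,
                           dt: float) -> np.ndarray:
    """Deterministic spike times from binned counts (spread within each bin)."""
    nz = np.flatnonzero(counts)
    out = []
    for t_idx in nz:
        k = int(counts[t_idx])
        out.append(times[t_idx] + dt * (np.arange(k) + 0.5) / k)
    return np.concatenate(out) if out else np.empty(0)


def write_session(
    path,
    trajectory: Trajectory,
    spikes: SpikeData,
    arena: Arena,
) -> None:
    """Write a session container (tracking + per-unit spike times)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["arena_radius"] = arena.radius
        f.attrs["arena_topology"] = arena.topology
        f.attrs["dt"] = trajectory.dt
        tr = f.create_group("tracking")
        tr.create_dataset("t", data=trajectory.times)
        tr.create_dataset("x", data=trajectory.positions[:, 0])
        tr.create_dataset("y", data=trajectory.positions[:, 1])
        units = f.create_group("units")
        for i in range(spikes.n_neurons):
            g = units.create_group(f"unit{int(spikes.unit_ids[i]):04d}")
            st = _counts_to_spike_times(spikes.counts[i], trajectory.times,
                                        trajectory.dt)
            g.create_dataset("spike_times", data=st)
            g.attrs["module"] = int(spikes.module_labels[i])
            if spikes.specs is not None:
                g.attrs["spacing"] = float(spikes.specs[i].spacing)


def read_session(
    path,
    min_spikes: int = 500,
) -> tuple[Trajectory, SpikeData, Arena]:
    """Read a session container back into in-memory objects.

    Spike times are binned onto the tracking clock.  Units with fewer than
    ``min_spikes`` total spikes are excluded (the standard single-unit
    inclusion criterion); set ``min_spikes=0`` to keep everything.  Missing
    /tracking or /units groups raise :class:`SchemaError` naming the group.
    """
    import h5py

    with h5py.File(path, "r") as f:
        if "tracking" not in f:
            raise SchemaError("session file has no /tracking group")
        if "units" not in f:
            raise SchemaError("session file has no /units group")
        tr = f["tracking"]
        for name in ("t", "x", "y"):
            if name not in tr:
                raise SchemaError(f"/tracking is missing dataset '{name}'")
        times = np.asarray(tr["t"])
        pos = np.stack([np.asarray(tr["x"]), np.asarray(tr["y"])], axis=1)
        dt = float(f.attrs.get("dt", np.median(np.diff(times))))
        arena = Arena(radius=float(f.attrs.get("arena_radius", 75.0)),
                      topology=str(f.attrs.get("arena_topology", "disk")))
        edges = np.concatenate([times, [times[-1] + dt]])
        counts_rows, labels, ids = [], [], []
        for k, name in enumerate(sorted(f["units"])):
            g = f["units"][name]
            if "spike_times" not in g:
                raise SchemaError(f"/units/{name} is missing 'spike_times'")
            st = np.asarray(g["spike_times"])
            if len(st) < min_spikes:
                continue
            idx = np.clip(np.searchsorted(edges, st, side="right") - 1,
                          0, len(times) - 1)
            row = np.zeros(len(times), dtype=np.int32)
            np.add.at(row, idx, 1)
            counts_rows.append(row)
            labels.append(int(g.attrs.get("module", -1)))
            ids.append(k)
        if not counts_rows:
            raise SchemaError("no units passed the minimum-spike criterion")
        trajectory = Trajectory(times=times, positions=pos, dt=dt)
        spikes = SpikeData(counts=np.stack(counts_rows),
                           module_labels=np.asarray(labels), dt=dt,
                           unit_ids=np.asarray(ids))
    return trajectory, spikes, arena
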