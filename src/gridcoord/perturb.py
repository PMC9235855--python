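"""Decode-time perturbations that create controlled inter-module incoordination.

Per-module spatial shifts (translations) and rotations of the rate maps are
applied at decoding time, leaving the spike trains untouched.  In
``independent`` mode every module draws its own perturbation, destroying
inter-module coherence; in ``identical`` mode a single draw is shared by all
modules, preserving coherence (exactly so on a torus, where a global
translation is a symmetry).  Spike-train time-bin permutation provides a
temporal-structure control with mean rates exactly preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd

from .arena import Arena, BinGrid
from .synthetic import GridCellSpec, SpikeData, idealized_tuning_curve

__all__ = [
    "ShiftSpec",
    "draw_shifts",
    "shift_rate_maps",
    "rotate_rate_maps",
    "permute_spikes",
    "sweep",
]


@dataclass(frozen=True)
class ShiftSpec:
    """A realized set of per-module perturbations.

    ``magnitude`` is the half-range alpha: translations draw each offset
    component uniformly from [-alpha, alpha] cm; rotations draw the angle
    uniformly from [-alpha, alpha] radians.  ``identical`` mode uses one draw
    for all modules.  Offsets are fixed for a whole run.
    """

    mode: str  # {"independent", "identical"}
    kind: str  # {"translate", "rotate"}
    magnitude: float
    module_ids: tuple[int, ...]
    offsets: np.ndarray = field(repr=False)  # (M, 2) cm or (M,) radians
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("independent", "identical"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.kind not in ("translate", "rotate"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude alpha must be >= 0")

    def offset_for(self, module_id: int) -> np.ndarray:
        k = self.module_ids.index(module_id)
        return np.atleast_1d(self.offsets[k])


def draw_shifts(
    module_ids: list[int],
    mode: str,
    kind: str,
    magnitude: float,
    seed: int | np.random.Generator | None = None,
) -> ShiftSpec:
    """Draw one realization of per-module shifts or rotations."""
    rng = np.random.default_rng(seed)
    n = len(module_ids)
    dim = 2 if kind == "translate" else 1
    if mode == "identical":
        one = rng.uniform(-magnitude, magnitude, size=dim)
        offs = np.repeat(one[None], n, axis=0)
    else:
        offs = rng.uniform(-magnitude, magnitude, size=(n, dim))
    if kind == "rotate":
        offs = offs[:, 0]
    return ShiftSpec(mode=mode, kind=kind, magnitude=float(magnitude),
                     module_ids=tuple(int(m) for m in module_ids),
                     offsets=offs,
                     seed=seed if isinstance(seed, int) else None)


def _perturbed_rates_from_specs(
    specs: list[GridCellSpec],
    grid: BinGrid,
    spec_shift: ShiftSpec,
) -> np.ndarray:
    """Evaluate idealized tuning curves under a shift/rotation, exactly.

    Translation by s evaluates f(r - s); bins whose source point r - s lies
    outside the arena are zeroed (they were vacated by the shift), matching
    the grid-based procedure but without resampling error.  Rotation by
    theta about the arena center evaluates f(R(-theta) r); on a disk the
    rotated source always stays inside the arena.  Torus arenas wrap instead
    of zero-filling.
    """
    arena = grid.arena
    centers = grid.centers
    out = np.empty((len(specs), len(centers)))
    for i, spec in enumerate(specs):
        off = spec_shift.offset_for(spec.module_id)
        if spec_shift.kind == "translate":
            src = centers - off[None, :]
        else:
            th = -float(off[0])
            rot = np.array([[np.cos(th), -np.sin(th)],
                            [np.sin(th), np.cos(th)]])
            src = centers @ rot.T
        rates = idealized_tuning_curve(spec, arena.wrap(src))
        if arena.topology == "disk":
            rates = np.where(arena.contains(src), rates, 0.0)
        out[i] = rates
    return out


def shift_rate_maps(
    rates: np.ndarray,
    module_labels: np.ndarray,
    grid: BinGrid,
    spec_shift: ShiftSpec,
    specs: list[GridCellSpec] | None = None,
) -> np.ndarray:
    """Per-module translation of (N, B) rate fields over the grid's valid bins.

    Idealized populations (``specs`` given) are shifted on the continuous
    tuning-curve representation (exact).  Measured maps are shifted by the
    nearest whole number of bins; vacated bins are zero-filled (then floored
    downstream).  Torus arenas wrap instead of zero-filling.
    """
    if spec_shift.kind != "translate":
        raise ValueError("shift_rate_maps expects a translate ShiftSpec")
    if grid.arena.topology == "torus":
        # integer-bin roll with wrap: a global (identical-mode) translation is
        # then an exact symmetry of the periodic decode
        return _shift_measured(rates, module_labels, grid, spec_shift)
    if specs is not None:
        return _perturbed_rates_from_specs(specs, grid, spec_shift)
    return _shift_measured(rates, module_labels, grid, spec_shift)


def _shift_measured(
    rates: np.ndarray,
    module_labels: np.ndarray,
    grid: BinGrid,
    spec_shift: ShiftSpec,
) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    out = np.empty_like(rates)
    mask = grid.mask
    for m in spec_shift.module_ids:
        sel = np.flatnonzero(np.asarray(module_labels) == m)
        if len(sel) == 0:
            continue
        off = spec_shift.offset_for(m)
        shift_bins = np.round(off / grid.bin_size).astype(int)  # (dx, dy)
        dense = np.zeros((len(sel),) + mask.shape)
        dense[:, mask] = rates[sel]
        rolled = np.roll(dense, (shift_bins[1], shift_bins[0]), axis=(1, 2))
        if grid.arena.topology == "disk":
            # zero the rows/cols wrapped around by roll (vacated bins)
            dy, dx = shift_bins[1], shift_bins[0]
            if dy > 0:
                rolled[:, :dy, :] = 0.0
            elif dy < 0:
                rolled[:, dy:, :] = 0.0
            if dx > 0:
                rolled[:, :, :dx] = 0.0
            elif dx < 0:
                rolled[:, :, dx:] = 0.0
            rolled[:, ~mask] = 0.0
        out[sel] = rolled[:, mask]
    return out


def rotate_rate_maps(
    rates: np.ndarray,
    module_labels: np.ndarray,
    grid: BinGrid,
    spec_shift: ShiftSpec,
    specs: list[GridCellSpec] | None = None,
) -> np.ndarray:
    """Per-module rotation of rate fields about the arena center.

    Idealized populations rotate the continuous tuning curve (exact);
    measured maps are resampled bilinearly, with out-of-support bins zeroed.
    """
    if spec_shift.kind != "rotate":
        raise ValueError("rotate_rate_maps expects a rotate ShiftSpec")
    if specs is not None:
        return _perturbed_rates_from_specs(specs, grid, spec_shift)
    from scipy.ndimage import map_coordinates

    rates = np.asarray(rates, dtype=float)
    out = np.empty_like(rates)
    mask = grid.mask
    cx, cy = grid.centers_xy
    gx, gy = np.meshgrid(cx, cy, indexing="xy")
    for m in spec_shift.module_ids:
        sel = np.flatnonzero(np.asarray(module_labels) == m)
        if len(sel) == 0:
            continue
        th = -float(spec_shift.offset_for(m)[0])
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sx = rot[0, 0] * gx + rot[0, 1] * gy
        sy = rot[1, 0] * gx + rot[1, 1] * gy
        # source coordinates in (row, col) index space
        col = (sx - cx[0]) / grid.bin_size
        row = (sy - cy[0]) / grid.bin_size
        dense = np.zeros(mask.shape)
        for i in sel:
            dense[mask] = rates[i]
            dense[~mask] = 0.0
            res = map_coordinates(dense, [row.ravel(), col.ravel()], order=1,
                                  mode="grid-wrap" if grid.arena.topology == "torus"
                                  else "constant", cval=0.0)
            out[i] = res.reshape(mask.shape)[mask]
    return out


def permute_spikes(
    spikes: SpikeData,
    scheme: str = "joint",
    seed: int | np.random.Generator | None = None,
) -> SpikeData:
    """Random permutation of time-bin order; per-neuron totals are preserved.

    ``joint``: one permutation applied to all neurons (population synchrony
    within a bin survives, temporal continuity does not).  ``per-neuron``:
    an independent permutation per neuron (synchrony is destroyed too).
    """
    rng = np.random.default_rng(seed)
    T = spikes.n_bins
    if scheme == "joint":
        perm = rng.permutation(T)
        counts = spikes.counts[:, perm]
    elif scheme == "per-neuron":
        counts = np.empty_like(spikes.counts)
        for i in range(spikes.n_neurons):
            counts[i] = spikes.counts[i, rng.permutation(T)]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    return _dc_replace(spikes, counts=counts)


def sweep(
    alphas: list[float],
    realizations: int,
    run_one,
    module_ids: list[int],
    mode: str = "independent",
    kind: str = "translate",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run a perturbation sweep: ``run_one(shift_spec)`` per (alpha, realization).

    ``run_one`` receives the realized :class:`ShiftSpec` and returns a dict of
    scalar results (e.g. L, MAE, per-module deltas).  Failed realizations are
    recorded with an ``error`` column rather than silently dropped.  Returns a
    tidy frame with one row per realization.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for alpha in alphas:
        for k in range(realizations):
            spec_shift = draw_shifts(module_ids, mode, kind, alpha, rng)
            row = {"alpha": float(alpha), "realization": k,
                   "mode": mode, "kind": kind}
            try:
                row.update(run_one(spec_shift))
            except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                row["error"] = repr(exc)
            rows.append(row)
    return pd.DataFrame(rows)
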