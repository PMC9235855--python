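"""Kernel decoder: instantaneous ML position from exponentially filtered spikes.

Each neuron's recent spikes are summarized by an exponentially weighted count
nu_i(t) (time constant tau = 100 ms); the log posterior over position is then

    log p({nu_i} | r) = c + sum_i nu_i log f_i(r)

(the occupancy term is absorbed into the constant under the dense,
translation-invariant receptive-field assumption).  Decoding all grid cells
jointly gives the multi-module estimate m_hat; decoding one module alone gives
an approximately periodic posterior whose ambiguity is resolved by searching
only a circular area around m_hat with diameter 0.9x the module spacing,
yielding the uni-module estimate u_hat_i.  The distances delta_i = |m_hat -
u_hat_i| and Delta_ij = |u_hat_i - u_hat_j| quantify inter-module coordination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .arena import Arena, BinGrid
from .maps import RATE_FLOOR
from .stats import sem_correlated
from .synthetic import SpikeData

__all__ = [
    "KernelCounts",
    "ModuleEstimates",
    "kernel_counts",
    "log_posterior",
    "multi_module_decode",
    "uni_module_decode",
    "decode_kernel",
    "coordination_distances",
]

DEFAULT_TAU = 0.1  # s
DEFAULT_AREA_FRAC = 0.9  # circular-area diameter as a fraction of spacing


def arena_displacement(arena: Arena, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Displacement a - b, wrapped to the nearest image on a torus."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if arena.topology == "torus":
        period = arena.period
        d = (d + period / 2.0) % period - period / 2.0
    return d


def arena_distance(arena: Arena, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = arena_displacement(arena, a, b)
    return np.hypot(d[..., 0], d[..., 1])


@dataclass
class KernelCounts:
    """Causal exponentially weighted spike counts nu_i(t), one row per neuron."""

    values: np.ndarray  # (N, T)
    tau: float
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("kernel counts must be non-negative")


def kernel_counts(spikes: SpikeData, tau: float = DEFAULT_TAU) -> KernelCounts:
    """Exponential filtering of the spike indicator series.

    nu_i(t) = sum_{t' <= t} exp(-(t - t')/tau) n_i(t'); a single spike at t0
    contributes 1 at t0 and e^-1 one time constant later.  For a stationary
    rate r the mean of nu is r*dt/(1 - e^(-dt/tau)) ~= r*tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    decay = np.exp(-spikes.dt / tau)
    values = lfilter([1.0], [1.0, -decay], spikes.counts.astype(float), axis=1)
    return KernelCounts(values=values, tau=tau, dt=spikes.dt)


def log_posterior(
    nu_t: np.ndarray,
    rates: np.ndarray,
    rate_floor: float = RATE_FLOOR,
) -> np.ndarray:
    """Log-likelihood field over bins (up to a constant) for one time bin.

    field(r) = sum_i nu_i log f_i(r); rates are floored to keep the logs
    finite on unvisited bins.
    """
    rates = np.maximum(np.asarray(rates, dtype=float), rate_floor)
    return np.asarray(nu_t, dtype=float) @ np.log(rates)


def _chunked_argmax_fields(
    nu: np.ndarray,
    log_rates: np.ndarray,
    chunk: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax over bins of nu(t) @ log_rates per time bin, plus tie flags."""
    N, T = nu.shape
    idx = np.empty(T, dtype=np.int64)
    ties = np.zeros(T, dtype=bool)
    for t0 in range(0, T, chunk):
        t1 = min(t0 + chunk, T)
        fields = nu[:, t0:t1].T @ log_rates  # (Tc, B)
        idx[t0:t1] = fields.argmax(axis=1)
        best = fields[np.arange(t1 - t0), idx[t0:t1]]
        ties[t0:t1] = (np.isclose(fields, best[:, None]).sum(axis=1) > 1)
    return idx, ties


def multi_module_decode(
    counts: KernelCounts,
    rates: np.ndarray,
    grid: BinGrid,
    rate_floor: float = RATE_FLOOR,
    chunk: int = 1024,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-module ML position m_hat(t) from the pooled grid-cell field.

    Returns (positions (T, 2), tie_flags (T,)).  Ties are broken toward the
    first bin index and flagged so downstream statistics can count them.
    """
    log_rates = np.log(np.maximum(np.asarray(rates, dtype=float), rate_floor))
    idx, ties = _chunked_argmax_fields(counts.values, log_rates, chunk)
    return grid.centers[idx], ties


def uni_module_decode(
    counts: KernelCounts,
    module_rates: np.ndarray,
    grid: BinGrid,
    m_hat: np.ndarray,
    spacing: float,
    area_frac: float = DEFAULT_AREA_FRAC,
    rate_floor: float = RATE_FLOOR,
    chunk: int = 1024,
) -> np.ndarray:
    """Uni-module ML position u_hat_i(t) within the circular search area.

    The module's log field (counts restricted to the module's neurons) is
    maximized over bins within a disk of diameter ``area_frac * spacing``
    centered on the multi-module estimate m_hat(t), so that exactly one
    posterior blob of the periodic uni-module field is in play.  Bins outside
    the arena are simply absent from the grid (the disk is clipped to the
    arena); an empty intersection falls back to the nearest valid bin.
    """
    log_rates = np.log(np.maximum(np.asarray(module_rates, dtype=float), rate_floor))
    centers = grid.centers
    arena = grid.arena
    radius = 0.5 * area_frac * spacing
    N, T = counts.values.shape
    out = np.empty((T, 2))
    for t0 in range(0, T, chunk):
        t1 = min(t0 + chunk, T)
        fields = counts.values[:, t0:t1].T @ log_rates  # (Tc, B)
        d = arena_distance(arena, centers[None, :, :], m_hat[t0:t1, None, :])
        inside = d <= radius
        empty = ~inside.any(axis=1)
        if empty.any():  # disk misses all bin centers; take the nearest bin
            nearest = d[empty].argmin(axis=1)
            inside[empty, nearest] = True
        masked = np.where(inside, fields, -np.inf)
        out[t0:t1] = centers[masked.argmax(axis=1)]
    return out


@dataclass
class ModuleEstimates:
    """Joint multi-module and per-module kernel-decoder estimates."""

    times: np.ndarray  # (T,) s
    m_hat: np.ndarray  # (T, 2) cm
    u_hat: np.ndarray  # (M, T, 2) cm
    module_ids: np.ndarray  # (M,)
    spacings: np.ndarray  # (M,)
    arena: Arena
    tie_flags: np.ndarray  # (T,)
    area_frac: float = DEFAULT_AREA_FRAC

    @property
    def delta(self) -> np.ndarray:
        """delta_i(t) = |m_hat(t) - u_hat_i(t)|, shape (M, T)."""
        return arena_distance(self.arena, self.u_hat, self.m_hat[None])

    @property
    def pair_delta(self) -> dict[tuple[int, int], np.ndarray]:
        """Delta_ij(t) = |u_hat_i(t) - u_hat_j(t)| for every module pair."""
        M = len(self.module_ids)
        out = {}
        for a in range(M):
            for b in range(a + 1, M):
                out[(int(self.module_ids[a]), int(self.module_ids[b]))] = (
                    arena_distance(self.arena, self.u_hat[a], self.u_hat[b])
                )
        return out


def decode_kernel(
    spikes: SpikeData,
    rates: np.ndarray,
    grid: BinGrid,
    tau: float = DEFAULT_TAU,
    area_frac: float = DEFAULT_AREA_FRAC,
    spacings: dict[int, float] | None = None,
    stride: int = 1,
    rate_floor: float = RATE_FLOOR,
    chunk: int = 1024,
) -> ModuleEstimates:
    """Full kernel-decoding pass: m_hat, per-module u_hat, at every bin.

    ``rates`` is the (N, B) rate matrix over valid grid bins (same order as
    ``spikes``).  ``spacings`` maps module id -> grid spacing (cm); when the
    spikes carry idealized specs it is inferred from them.  ``stride``
    evaluates the estimates every ``stride``-th tracking bin (the causal
    kernel counts are always computed at full resolution first).
    """
    if spacings is None:
        if spikes.specs is None:
            raise ValueError("spacings required when spikes carry no specs")
        spacings = {}
        for s in spikes.specs:
            spacings.setdefault(s.module_id, s.spacing)
    counts = kernel_counts(spikes, tau=tau)
    sub = KernelCounts(values=counts.values[:, ::stride], tau=tau, dt=spikes.dt)
    m_hat, ties = multi_module_decode(sub, rates, grid, rate_floor, chunk)
    module_ids = np.array(sorted(spacings))
    u_hat = np.empty((len(module_ids), sub.values.shape[1], 2))
    for k, m in enumerate(module_ids):
        sel = spikes.module_indices(int(m))
        sub_m = KernelCounts(values=sub.values[sel], tau=tau, dt=spikes.dt)
        u_hat[k] = uni_module_decode(
            sub_m, np.asarray(rates)[sel], grid, m_hat, spacings[int(m)],
            area_frac, rate_floor, chunk)
    times = np.arange(spikes.n_bins)[::stride] * spikes.dt
    return ModuleEstimates(
        times=times, m_hat=m_hat, u_hat=u_hat, module_ids=module_ids,
        spacings=np.array([spacings[int(m)] for m in module_ids]),
        arena=grid.arena, tie_flags=ties, area_frac=area_frac,
    )


def coordination_distances(
    estimates: ModuleEstimates,
    moving_mask: np.ndarray | None = None,
) -> dict:
    """Time-mean delta_i and Delta_ij with autocorrelation-corrected SEMs.

    ``moving_mask`` is evaluated on the estimate clock (already strided).
    Per-time-bin samples are retained for conditional-distribution analyses.
    """
    T = len(estimates.times)
    sel = np.ones(T, dtype=bool) if moving_mask is None else np.asarray(moving_mask)
    if not sel.any():
        raise ValueError("no time bins selected")
    delta = estimates.delta
    rows = []
    for k, m in enumerate(estimates.module_ids):
        series = delta[k, sel]
        rows.append({"module": int(m), "spacing_cm": float(estimates.spacings[k]),
                     "mean_delta_cm": float(series.mean()),
                     "sem_cm": sem_correlated(series)})
    pair_rows = []
    pair_samples = {}
    for (a, b), series_full in estimates.pair_delta.items():
        series = series_full[sel]
        pair_rows.append({"module_i": a, "module_j": b,
                          "mean_Delta_cm": float(series.mean()),
                          "sem_cm": sem_correlated(series)})
        pair_samples[(a, b)] = series
    return {
        "delta": pd.DataFrame(rows),
        "pair": pd.DataFrame(pair_rows),
        "delta_samples": delta[:, sel],
        "pair_samples": pair_samples,
        "mask": sel,
    }
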