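"""Recursive Bayesian position decoding and the spike-train likelihood.

The Markov decoder alternates a Gaussian-displacement motion prior
(per-dimension variance 4 cm² per 1/120-s step) with an independent-Poisson
emission model over arena bins, normalizing the posterior at every step.  The
running product of the normalizers Z(t) equals the likelihood of the
simultaneous spike trains marginalized over all continuous trajectories
(forward algorithm), so the average log normalizer

    L = <log Z>_t

measures how well the population activity is explained by *some* trajectory,
independently of the true one.  Incoherent populations (e.g. modules shifted
independently) admit no such trajectory and score a lower L.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter
from scipy.special import gammaln

from .arena import BinGrid
from .maps import RATE_FLOOR
from .stats import sem_correlated
from .synthetic import SpikeData

__all__ = [
    "TransitionModel",
    "MarkovResult",
    "emission_log_likelihood",
    "decode_markov",
    "forward_filter_dense",
    "avg_log_likelihood",
    "rate_adjust",
]

DEFAULT_STEP_VARIANCE = 4.0  # cm^2 per dimension per time step
DEFAULT_BURN_IN = 5.0  # s excluded from L (uninformative uniform start)

_TINY = 1e-290  # floor on propagated mass; guards kernel-truncation zeros


@dataclass(frozen=True)
class TransitionModel:
    """Gaussian displacement prior for one tracking time step.

    ``step_variance`` is the per-dimension variance (cm²) of the displacement
    within one Δt; at Δt = 1/120 s this realizes the random-walk prior of the
    marginalized likelihood.  On a disk the kernel is truncated at the wall
    and renormalized per source bin (the transition stays stochastic); on a
    torus it wraps, removing boundary effects entirely.
    """

    step_variance: float = DEFAULT_STEP_VARIANCE
    truncate: float = 6.0  # kernel support in SDs

    def __post_init__(self) -> None:
        if self.step_variance <= 0:
            raise ValueError("step_variance must be positive")

    def sigma_bins(self, grid: BinGrid) -> float:
        return float(np.sqrt(self.step_variance) / grid.bin_size)

    def operator(self, grid: BinGrid):
        """Return ``propagate(p)`` mapping dense posteriors (..., H, W) one
        step forward under the boundary-handled transition kernel."""
        sigma = self.sigma_bins(grid)
        mask = grid.mask
        if grid.arena.topology == "torus":
            def propagate(p: np.ndarray) -> np.ndarray:
                return gaussian_filter(p, sigma, mode="wrap",
                                       truncate=self.truncate, axes=(-2, -1))
            return propagate
        norm = gaussian_filter(mask.astype(float), sigma, mode="constant",
                               truncate=self.truncate)
        inv_norm = np.where(mask, 1.0 / np.maximum(norm, 1e-300), 0.0)

        def propagate(p: np.ndarray) -> np.ndarray:
            out = gaussian_filter(p * inv_norm, sigma, mode="constant",
                                  truncate=self.truncate, axes=(-2, -1))
            return out * mask
        return propagate

    def matrix(self, grid: BinGrid) -> np.ndarray:
        """Dense (B, B) transition matrix over valid bins: column r' holds
        p(r | r').  Built by pushing unit masses through the operator; columns
        sum to 1.  Intended for small grids (tests, oracles)."""
        propagate = self.operator(grid)
        B = grid.n_valid
        mat = np.empty((B, B))
        basis = np.zeros(grid.shape)
        iy, ix = np.nonzero(grid.mask)
        for j in range(B):
            basis[iy[j], ix[j]] = 1.0
            mat[:, j] = propagate(basis)[grid.mask]
            basis[iy[j], ix[j]] = 0.0
        return mat


@dataclass
class MarkovResult:
    """Per-step normalizers and MLE positions from the Markov decoder."""

    log_z: np.ndarray  # (T,) or (R, T)
    mle_positions: np.ndarray  # (T, 2) or (R, T, 2)
    grid: BinGrid
    dt: float

    @property
    def batched(self) -> bool:
        return self.log_z.ndim == 2

    def realization(self, r: int) -> "MarkovResult":
        return MarkovResult(log_z=self.log_z[r], mle_positions=self.mle_positions[r],
                            grid=self.grid, dt=self.dt)


def emission_log_likelihood(
    counts_t: np.ndarray,
    rates: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Log Poisson emission field over bins for a single time bin.

    log p_S(r) = sum_i [ n_i log(f_i(r) dt) - f_i(r) dt - log n_i! ]
    with rates floored upstream so the field is finite everywhere.
    """
    counts_t = np.asarray(counts_t, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be strictly positive (apply a rate floor)")
    log_rates = np.log(rates)
    field = counts_t @ log_rates
    field += counts_t.sum() * np.log(dt)
    field -= dt * rates.sum(axis=0)
    field -= gammaln(counts_t + 1.0).sum()
    return field


def _as_batched_rates(rates: np.ndarray) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    if rates.ndim == 2:
        rates = rates[None]
    if rates.ndim != 3:
        raise ValueError("rates must be (N, B) or (R, N, B)")
    return rates


def decode_markov(
    spikes: SpikeData,
    rates: np.ndarray,
    grid: BinGrid,
    transition: TransitionModel | None = None,
    initial_prior: np.ndarray | None = None,
    rate_floor: float = RATE_FLOOR,
    chunk: int = 512,
) -> MarkovResult:
    """Run the Markov decoder over a whole session.

    Parameters
    ----------
    spikes
        Binned population spike counts.
    rates
        Firing-rate fields over the valid bins of ``grid``: shape (N, B), or
        (R, N, B) to decode R map realizations (e.g. independent shift draws)
        against the same spike trains in one pass.
    transition
        Motion prior; defaults to the 4-cm²-per-step Gaussian.
    initial_prior
        Probability over valid bins at t=0 (default uniform).

    Returns a :class:`MarkovResult` with the per-step log normalizers log Z(t)
    (whose cumulative sum is the log marginal likelihood of the spike trains)
    and the per-step MLE positions.  Computation is carried in scaled linear
    space with per-step renormalization; log Z bookkeeping is exact.
    """
    transition = transition or TransitionModel()
    rates_b = _as_batched_rates(rates)
    if rate_floor is not None:
        rates_b = np.maximum(rates_b, rate_floor)
    R, N, B = rates_b.shape
    if N != spikes.n_neurons:
        raise ValueError("rates row count must match number of neurons")
    if B != grid.n_valid:
        raise ValueError("rates must cover the valid bins of the grid")
    T = spikes.n_bins
    dt = spikes.dt
    mask = grid.mask
    propagate = transition.operator(grid)

    log_rates = np.log(rates_b)  # (R, N, B)
    neg_sumrate = -dt * rates_b.sum(axis=1)  # (R, B)
    counts_csr = sparse.csr_matrix(spikes.counts.T.astype(np.float64))  # (T, N)
    tot_counts = np.asarray(spikes.counts.sum(axis=0), dtype=float)  # (T,)
    gammaln_term = gammaln(spikes.counts.astype(np.float64) + 1.0).sum(axis=0)
    const_t = tot_counts * np.log(dt) - gammaln_term  # (T,)

    if initial_prior is None:
        prior_flat = np.full(B, 1.0 / B)
    else:
        prior_flat = np.asarray(initial_prior, dtype=float)
        prior_flat = prior_flat / prior_flat.sum()

    p = np.zeros((R,) + mask.shape)
    p[:, mask] = prior_flat  # shared start across realizations
    log_z = np.empty((R, T))
    mle_idx = np.empty((R, T), dtype=np.int64)

    first = True
    for t0 in range(0, T, chunk):
        t1 = min(t0 + chunk, T)
        block = counts_csr[t0:t1]  # (Tc, N)
        # (R, Tc, B): spike-weighted log-rate fields for the chunk
        log_e = np.empty((R, t1 - t0, B))
        for r in range(R):
            log_e[r] = block @ log_rates[r]
        log_e += neg_sumrate[:, None, :]
        for k, t in enumerate(range(t0, t1)):
            if first:
                q = p  # t = 0: posterior = prior * emission, no propagation
                first = False
            else:
                q = propagate(p)
                np.maximum(q, _TINY, out=q, where=mask[None])
            le = log_e[:, k]  # (R, B)
            m = le.max(axis=1)
            w = np.zeros_like(q)
            w[:, mask] = np.exp(le - m[:, None])
            w *= q
            tot = w.sum(axis=(1, 2))
            log_z[:, t] = np.log(tot) + m + const_t[t]
            p = w / tot[:, None, None]
            flat = p[:, mask]
            mle_idx[:, t] = flat.argmax(axis=1)
    centers = grid.centers
    mle_positions = centers[mle_idx]
    if np.asarray(rates).ndim == 2:
        return MarkovResult(log_z=log_z[0], mle_positions=mle_positions[0],
                            grid=grid, dt=dt)
    return MarkovResult(log_z=log_z, mle_positions=mle_positions, grid=grid, dt=dt)


def forward_filter_dense(
    log_emissions: np.ndarray,
    transition: np.ndarray,
    prior: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward algorithm with an explicit (B, B) transition matrix.

    Reference implementation on arbitrary state spaces (used for oracle
    cross-checks on tiny instances).  Returns (log_z per step, final posterior).
    The first step applies emission only; transitions act between steps.
    """
    log_emissions = np.asarray(log_emissions, dtype=float)
    T, B = log_emissions.shape
    p = np.asarray(prior, dtype=float)
    p = p / p.sum()
    log_z = np.empty(T)
    for t in range(T):
        if t > 0:
            p = transition @ p
        le = log_emissions[t]
        m = le.max()
        w = p * np.exp(le - m)
        tot = w.sum()
        log_z[t] = np.log(tot) + m
        p = w / tot
    return log_z, p


def avg_log_likelihood(
    result: MarkovResult,
    moving_mask: np.ndarray | None = None,
    burn_in: float = DEFAULT_BURN_IN,
) -> tuple[float, float]:
    """Average log normalizer L = <log Z> over moving bins, with its SEM.

    Only time bins where the animal moves at >= 3 cm/s (``moving_mask``)
    enter the average; the first ``burn_in`` seconds are excluded so the
    uninformative uniform start does not bias L.  The SEM accounts for the
    temporal autocorrelation of log Z.  Raises on an empty selection.
    """
    if result.batched:
        raise ValueError("pass a single realization (use result.realization(r))")
    T = len(result.log_z)
    sel = np.ones(T, dtype=bool) if moving_mask is None else np.asarray(moving_mask)
    sel = sel.copy()
    sel[: int(round(burn_in / result.dt))] = False
    if not sel.any():
        raise ValueError("no time bins selected for the likelihood average")
    series = result.log_z[sel]
    return float(series.mean()), sem_correlated(series)


def rate_adjust(
    spikes_a: SpikeData,
    spikes_b: SpikeData,
    moving_a: np.ndarray,
    moving_b: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> tuple[SpikeData, SpikeData]:
    """Match mean firing rates across two conditions by thinning spikes.

    For every neuron, separately for still (< 3 cm/s) and moving (>= 3 cm/s)
    time bins, spikes are randomly omitted in the condition with the higher
    mean rate until the expected rates match.  Thinning only removes spikes;
    identical inputs pass through unchanged.
    """
    if spikes_a.n_neurons != spikes_b.n_neurons:
        raise ValueError("conditions must share the same neuron set")
    rng = np.random.default_rng(seed)
    counts_a = spikes_a.counts.copy()
    counts_b = spikes_b.counts.copy()
    for stratum_a, stratum_b in (
        (np.asarray(moving_a), np.asarray(moving_b)),
        (~np.asarray(moving_a), ~np.asarray(moving_b)),
    ):
        na, nb = stratum_a.sum(), stratum_b.sum()
        if na == 0 or nb == 0:
            continue
        tot_a = counts_a[:, stratum_a].sum(axis=1).astype(float)
        tot_b = counts_b[:, stratum_b].sum(axis=1).astype(float)
        rate_a, rate_b = tot_a / na, tot_b / nb
        for i in range(spikes_a.n_neurons):
            if rate_a[i] > rate_b[i] > 0 or (rate_a[i] > 0 and rate_b[i] == 0):
                keep = rate_b[i] / rate_a[i] if rate_a[i] > 0 else 1.0
                counts_a[i, stratum_a] = rng.binomial(
                    counts_a[i, stratum_a], keep)
            elif rate_b[i] > rate_a[i]:
                keep = rate_a[i] / rate_b[i]
                counts_b[i, stratum_b] = rng.binomial(
                    counts_b[i, stratum_b], keep)
    out_a = _dc_replace(spikes_a, counts=counts_a)
    out_b = _dc_replace(spikes_b, counts=counts_b)
    return out_a, out_b
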