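"""Statistics layer: correlations, decoding errors, nulls, and SEMs.

Holds the error metrics (MAE and its chance level), the null calibration for
the module coordination distances, spike-rate pair correlations, the
small/large error-segment extraction, conditional distributions of the
coordination distances given the decoding error, and the
autocorrelation-corrected standard error used for all time-series means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .arena import Arena
from .synthetic import SpikeData, Trajectory

__all__ = [
    "sem_correlated",
    "mae",
    "null_mae",
    "null_delta",
    "null_delta_closed_form",
    "uniform_pair_distance_closed_form",
    "pairwise_correlations",
    "lagged_group_correlations",
    "ErrorSegments",
    "error_segments",
    "conditional_distributions",
]


# ---------------------------------------------------------------------------
# autocorrelation-corrected SEM
# ---------------------------------------------------------------------------

def sem_correlated(signal: np.ndarray, acf_threshold: float = 0.15) -> float:
    """SEM of a temporally correlated, stationary time series.

    The variance of the mean uses the autocovariance sum
    Var = ACF0 + 2 * sum_i ACFi, truncated at the first lag where
    ACFi <= ``acf_threshold`` * ACF0 (biased ACF estimator, divide by n).
    Independent samples reduce to the classical SEM; a constant signal has
    SEM 0.  Raises for fewer than 2 samples.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples for an SEM")
    x = x - x.mean()
    acf0 = float(np.mean(x * x))
    if acf0 == 0.0:
        return 0.0
    # biased autocovariance via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    var = acf0
    for k in range(1, n):
        if acov[k] <= acf_threshold * acf0:
            break
        var += 2.0 * acov[k]
    var = max(var, 0.0)
    return float(np.sqrt(var / n))


# ---------------------------------------------------------------------------
# decoding error and nulls
# ---------------------------------------------------------------------------

def mae(
    decoded: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean Euclidean distance (cm) between decoded and true positions.

    Returns (MAE, SEM) over the masked time bins; the SEM accounts for the
    autocorrelation of the error series.  Raises on an empty mask.
    """
    decoded = np.asarray(decoded, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if decoded.shape != truth.shape:
        raise ValueError("decoded and true positions must align")
    err = np.hypot(*(decoded - truth).T)
    if mask is not None:
        err = err[np.asarray(mask)]
    if len(err) == 0:
        raise ValueError("no time bins selected")
    return float(err.mean()), sem_correlated(err)


def uniform_pair_distance_closed_form(radius: float) -> float:
    """Mean distance between two independent uniform points in a disk."""
    return 128.0 * radius / (45.0 * np.pi)


def null_mae(
    trajectory: Trajectory,
    arena: Arena,
    realizations: int = 30,
    seed: int | np.random.Generator | None = None,
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Chance-level MAE: decoded positions drawn uniformly in the arena.

    Monte-Carlo over ``realizations`` independent draws of a full-length
    uniform position series; returns the mean of the per-realization MAEs and
    their SEM.  For near-uniform trajectory coverage this approaches the
    closed form 128 R / (45 pi) ≈ 0.905 R.
    """
    rng = np.random.default_rng(seed)
    pos = trajectory.positions if mask is None else trajectory.positions[mask]
    n = len(pos)
    vals = np.empty(realizations)
    for k in range(realizations):
        if arena.topology == "torus":
            draws = rng.uniform(0.0, arena.period, size=(n, 2))
            d = np.abs(draws - np.mod(pos, arena.period))
            d = np.minimum(d, arena.period - d)
            vals[k] = np.hypot(d[:, 0], d[:, 1]).mean()
        else:
            r = arena.radius * np.sqrt(rng.uniform(size=n))
            th = rng.uniform(0, 2 * np.pi, size=n)
            draws = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
            vals[k] = np.hypot(*(draws - pos).T).mean()
    sem = vals.std(ddof=1) / np.sqrt(realizations) if realizations > 1 else 0.0
    return float(vals.mean()), float(sem)


def null_delta_closed_form(spacing: float, area_frac: float = 0.9) -> float:
    """Chance-level delta_i: (2/3) * (area_frac/2) * spacing."""
    return (2.0 / 3.0) * (area_frac / 2.0) * spacing


def null_delta(
    spacings: np.ndarray,
    area_frac: float = 0.9,
    realizations: int = 30,
    draws_per_realization: int = 20000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Chance-level delta_i per module by Monte Carlo.

    The uni-module estimate is replaced by a uniform draw within the module's
    circular search area (radius ``area_frac/2 * spacing``); the mean distance
    to the area center is (2/3) of that radius.  Returns a frame with
    Monte-Carlo mean, SEM over realizations, and the closed form.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for m, lam in enumerate(np.atleast_1d(spacings)):
        radius = 0.5 * area_frac * lam
        means = np.empty(realizations)
        for k in range(realizations):
            r = radius * np.sqrt(rng.uniform(size=draws_per_realization))
            means[k] = r.mean()
        sem = means.std(ddof=1) / np.sqrt(realizations) if realizations > 1 else 0.0
        rows.append({
            "module": m,
            "spacing_cm": float(lam),
            "null_delta_cm": float(means.mean()),
            "sem_cm": float(sem),
            "closed_form_cm": null_delta_closed_form(lam, area_frac),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spike-rate correlations
# ---------------------------------------------------------------------------

def _smooth_counts(spikes: SpikeData, sigma: float) -> np.ndarray:
    sigma_bins = sigma / spikes.dt
    return gaussian_filter1d(spikes.counts.astype(float), sigma_bins, axis=1,
                             mode="nearest")


def pairwise_correlations(spikes: SpikeData, sigma: float = 0.05) -> pd.DataFrame:
    """Zero-lag Pearson correlations of smoothed spike trains, all pairs.

    Trains are smoothed with a Gaussian kernel (sigma 50 ms by default);
    pairs are labelled intra- or inter-module from the module labels.
    Zero-variance trains give NaN coefficients (flagged, not dropped).
    """
    if spikes.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    sm = _smooth_counts(spikes, sigma)
    sd = sm.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sm)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    ii, jj = np.triu_indices(spikes.n_neurons, k=1)
    labels = spikes.module_labels
    return pd.DataFrame({
        "i": ii,
        "j": jj,
        "r": corr[ii, jj],
        "intra_module": labels[ii] == labels[jj],
    })


def lagged_group_correlations(
    spikes: SpikeData,
    n_groups: int = 10,
    max_lag: float = 0.5,
    lag_step: float = 0.1,
    sigma: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean absolute pair correlation versus time lag, intra and inter module.

    Neurons are split into ``n_groups`` groups with (approximately) equal
    module composition; within each group all intra- and inter-module pairs
    are correlated at each lag, the absolute coefficients are averaged per
    group, and mean ± SEM over groups is reported per lag.  Fewer neurons
    than groups reduces the group count (with a warning in the result).
    """
    rng = np.random.default_rng(seed)
    labels = spikes.module_labels
    n_groups = min(n_groups, spikes.n_neurons // 2) or 1
    groups: list[list[int]] = [[] for _ in range(n_groups)]
    for m in np.unique(labels):
        idx = np.flatnonzero(labels == m)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            groups[k % n_groups].append(int(i))
    sm = _smooth_counts(spikes, sigma)
    sm = sm - sm.mean(axis=1, keepdims=True)
    sd = sm.std(axis=1)
    lags = np.arange(0.0, max_lag + 1e-9, lag_step)
    lag_bins = np.round(lags / spikes.dt).astype(int)
    T = spikes.n_bins
    rows = []
    for lag_s, lag_b in zip(lags, lag_bins):
        per_group: dict[str, list[float]] = {"intra": [], "inter": []}
        for members in groups:
            acc: dict[str, list[float]] = {"intra": [], "inter": []}
            for a_pos, i in enumerate(members):
                for j in members[a_pos + 1:]:
                    if sd[i] == 0 or sd[j] == 0:
                        continue
                    x = sm[i, : T - lag_b] if lag_b else sm[i]
                    y = sm[j, lag_b:] if lag_b else sm[j]
                    r = float(np.mean(x * y) / (x.std() * y.std() + 1e-300))
                    kind = "intra" if labels[i] == labels[j] else "inter"
                    acc[kind].append(abs(r))
            for kind in ("intra", "inter"):
                if acc[kind]:
                    per_group[kind].append(float(np.mean(acc[kind])))
        for kind in ("intra", "inter"):
            vals = np.asarray(per_group[kind])
            rows.append({
                "lag_s": float(lag_s),
                "kind": kind,
                "mean_abs_r": float(vals.mean()) if len(vals) else np.nan,
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1 else np.nan,
                "n_groups": len(vals),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# error segments and conditional distributions
# ---------------------------------------------------------------------------

@dataclass
class ErrorSegments:
    """Non-overlapping small/large smoothed-error segments (index intervals)."""

    small: list[tuple[int, int]]
    large: list[tuple[int, int]]
    smoothed_error: np.ndarray
    large_cutoff: float
    thresholds: dict

    def mask(self, which: str) -> np.ndarray:
        out = np.zeros(len(self.smoothed_error), dtype=bool)
        for a, b in getattr(self, which):
            out[a:b] = True
        return out


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return [(int(a), int(b)) for a, b in zip(starts, ends) if b - a >= min_len]


def error_segments(
    errors: np.ndarray,
    dt: float,
    small_max: float = 10.0,
    large_min: float = 20.0,
    large_cutoff_quantile: float = 0.8,
    min_duration: float = 1.0,
    sigma: float = 0.05,
) -> ErrorSegments:
    """Extract small- and large-error periods from a decoding-error series.

    The error is first smoothed with a Gaussian kernel (sigma 50 ms).  Small
    segments are runs of >= ``min_duration`` s with smoothed error <= 10 cm;
    large segments are runs with smoothed error in [20 cm, cutoff], where the
    cutoff is the 80% point of the cumulative smoothed-error distribution
    (bins above it are discarded).  Empty classes are allowed.
    """
    errors = np.asarray(errors, dtype=float)
    se = gaussian_filter1d(errors, sigma / dt, mode="nearest")
    cutoff = float(np.quantile(se, large_cutoff_quantile))
    min_len = max(1, int(round(min_duration / dt)))
    small = _runs(se <= small_max, min_len)
    large = _runs((se >= large_min) & (se <= cutoff), min_len)
    return ErrorSegments(
        small=small, large=large, smoothed_error=se, large_cutoff=cutoff,
        thresholds={"small_max": small_max, "large_min": large_min,
                    "large_cutoff_quantile": large_cutoff_quantile,
                    "min_duration": min_duration, "sigma": sigma},
    )


def conditional_distributions(
    distance_samples: np.ndarray,
    mae_samples: np.ndarray,
    n_mae_bins: int = 5,
    n_hist_bins: int = 25,
) -> pd.DataFrame:
    """Normalized distributions of a coordination distance per MAE bin.

    Joint per-time-bin samples of (distance, instantaneous decoding error)
    are split into MAE quantile bins; within each bin the distance histogram
    is normalized to unit mass.  Under tight module coordination the
    conditional distributions are nearly identical across MAE bins.
    """
    d = np.asarray(distance_samples, dtype=float)
    e = np.asarray(mae_samples, dtype=float)
    if d.shape != e.shape:
        raise ValueError("distance and MAE samples must align")
    qs = np.quantile(e, np.linspace(0, 1, n_mae_bins + 1))
    qs[-1] += 1e-9
    edges = np.linspace(0.0, max(d.max(), 1e-9), n_hist_bins + 1)
    rows = []
    for b in range(n_mae_bins):
        sel = (e >= qs[b]) & (e < qs[b + 1])
        if not sel.any():
            continue
        hist, _ = np.histogram(d[sel], bins=edges)
        mass = hist / hist.sum() if hist.sum() else hist.astype(float)
        for k in range(n_hist_bins):
            rows.append({
                "mae_bin": b,
                "mae_lo": float(qs[b]),
                "mae_hi": float(qs[b + 1]),
                "distance_mid": float(0.5 * (edges[k] + edges[k + 1])),
                "density": float(mass[k]),
                "n_samples": int(sel.sum()),
            })
    return pd.DataFrame(rows)
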