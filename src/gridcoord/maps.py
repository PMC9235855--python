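"""Rate maps and single-cell spatial metrics.

Rate maps are kernel-smoothed ratios of spike density to occupancy density
(Gaussian kernel, per-dimension variance 25 cm² by default), computed from
time bins where the animal moves at >= 3 cm/s.  From a map the module derives
the spatial autocorrelogram, the hexagonality (gridness) score in [-2, 2],
and the spatial information content in bits/spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, rotate as nd_rotate
from scipy.signal import fftconvolve

from .arena import Arena, BinGrid
from .synthetic import GridCellSpec, SpikeData, Trajectory, idealized_tuning_curve

__all__ = [
    "RateMap",
    "Autocorrelogram",
    "compute_rate_map",
    "tuning_rate_map",
    "rate_matrix_from_specs",
    "spatial_autocorrelogram",
    "gridness_score",
    "spatial_information",
    "occupancy_map",
]

DEFAULT_KERNEL_VARIANCE = 25.0  # cm^2 per dimension
SPEED_MIN = 3.0  # cm/s
CLASSIFICATION_BIN = 9.0  # cm, for module-classification maps
DECODING_BIN = 3.0  # cm, for decoder posteriors and tuning evaluation
RATE_FLOOR = 1e-3  # Hz, floor applied when maps feed log-likelihoods


@dataclass
class RateMap:
    """Firing rate (Hz) over arena bins; NaN where undefined or outside."""

    rates: np.ndarray
    grid: BinGrid
    kernel_variance: float = DEFAULT_KERNEL_VARIANCE

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != self.grid.shape:
            raise ValueError("rates shape must match the bin grid")

    @property
    def valid(self) -> np.ndarray:
        return self.grid.mask & np.isfinite(self.rates)

    @property
    def bin_size(self) -> float:
        return self.grid.bin_size

    def flat(self, floor: float | None = None) -> np.ndarray:
        """Rates over valid grid bins, flattened; NaN bins -> 0 (unvisited)."""
        vals = np.where(np.isfinite(self.rates), self.rates, 0.0)[self.grid.mask]
        if floor is not None:
            vals = np.maximum(vals, floor)
        return vals

    def mean_rate(self, occupancy: np.ndarray | None = None) -> float:
        v = self.valid
        if occupancy is None:
            return float(np.nanmean(self.rates[v]))
        p = occupancy[v] / occupancy[v].sum()
        return float(np.sum(p * self.rates[v]))


@dataclass
class Autocorrelogram:
    """2-D spatial autocorrelation (Pearson r per displacement) of a rate map."""

    values: np.ndarray  # (2H-1, 2W-1); NaN where overlap too small
    bin_size: float
    center_mask_radius: int = 3  # bins, for feature extraction
    degenerate: bool = False

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)

    def radius_grid(self) -> np.ndarray:
        cy, cx = self.center
        yy, xx = np.indices(self.values.shape)
        return np.hypot(yy - cy, xx - cx)

    def masked(self) -> np.ndarray:
        """Feature view: center disk (3-bin radius) and out-of-circle corners
        removed (NaN).  The outer cutoff is the inscribed circle of the matrix."""
        rad = self.radius_grid()
        out = self.values.copy()
        out[rad <= self.center_mask_radius] = np.nan
        out[rad > min(self.center)] = np.nan
        return out


def occupancy_map(
    trajectory: Trajectory,
    grid: BinGrid,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Time spent (s) per grid bin, restricted to masked time bins."""
    pos = trajectory.positions if mask is None else trajectory.positions[mask]
    idx = grid.position_to_index(pos)
    occ = np.zeros(grid.shape)
    np.add.at(occ, (idx[:, 0], idx[:, 1]), trajectory.dt)
    return occ


def compute_rate_map(
    counts: np.ndarray,
    trajectory: Trajectory,
    grid: BinGrid,
    kernel_variance: float = DEFAULT_KERNEL_VARIANCE,
    speed_min: float = SPEED_MIN,
) -> RateMap:
    """Kernel rate-map estimate for one neuron.

    lambda(x) = sum_j g(x_j - x) / (dt * sum_t g(y_t - x)) with a Gaussian g
    (per-dimension variance ``kernel_variance``), using only time bins with
    speed >= ``speed_min``.  Bins with (smoothed) zero occupancy are NaN.

    Raises ``ValueError`` if no time bin passes the speed filter.
    """
    counts = np.asarray(counts)
    if counts.shape != (len(trajectory),):
        raise ValueError("counts must be a per-time-bin vector for one neuron")
    moving = trajectory.moving_mask(speed_min) if speed_min > 0 else np.ones(
        len(trajectory), dtype=bool)
    if not moving.any():
        raise ValueError("no moving time bins; session unusable for rate maps")
    idx = grid.position_to_index(trajectory.positions[moving])
    spike_hist = np.zeros(grid.shape)
    np.add.at(spike_hist, (idx[:, 0], idx[:, 1]), counts[moving].astype(float))
    occ_hist = np.zeros(grid.shape)
    np.add.at(occ_hist, (idx[:, 0], idx[:, 1]), trajectory.dt)
    sigma_bins = np.sqrt(kernel_variance) / grid.bin_size
    num = gaussian_filter(spike_hist, sigma_bins, mode="constant")
    den = gaussian_filter(occ_hist, sigma_bins, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    rates[~grid.mask] = np.nan
    return RateMap(rates=rates, grid=grid, kernel_variance=kernel_variance)


def tuning_rate_map(spec: GridCellSpec, grid: BinGrid) -> RateMap:
    """Evaluate an idealized tuning curve on a bin grid (no estimation noise)."""
    rates = np.full(grid.shape, np.nan)
    rates[grid.mask] = idealized_tuning_curve(spec, grid.centers, arena=grid.arena)
    return RateMap(rates=rates, grid=grid, kernel_variance=0.0)


def rate_matrix_from_specs(
    specs: list[GridCellSpec],
    grid: BinGrid,
    floor: float | None = None,
) -> np.ndarray:
    """(N, B) firing rates of idealized cells over the valid bins of a grid."""
    centers = grid.centers
    out = np.empty((len(specs), len(centers)))
    for i, spec in enumerate(specs):
        out[i] = idealized_tuning_curve(spec, centers, arena=grid.arena)
    if floor is not None:
        np.maximum(out, floor, out=out)
    return out


def rate_matrix_from_maps(maps: list[RateMap], floor: float | None = None) -> np.ndarray:
    """(N, B) rates over valid bins from estimated rate maps (NaN -> 0)."""
    return np.stack([m.flat(floor=floor) for m in maps])


# ---------------------------------------------------------------------------
# autocorrelogram and gridness
# ---------------------------------------------------------------------------

def _correlate_full(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross-correlation sums over all displacements (full mode)."""
    return fftconvolve(a, b[::-1, ::-1], mode="full")


def spatial_autocorrelogram(rate_map: RateMap, min_overlap: int = 20) -> Autocorrelogram:
    """Pearson-normalized 2-D spatial autocorrelation of a rate map.

    Each displacement bin holds the Pearson correlation between the map and
    its shifted copy over their overlapping valid bins; displacements with
    fewer than ``min_overlap`` overlapping bins are NaN.  A constant map has
    no defined correlation and yields a flagged degenerate result.
    """
    valid = rate_map.valid
    if valid.sum() < 25:
        raise ValueError("rate map needs at least a 5x5 set of valid bins")
    x = np.where(valid, rate_map.rates, 0.0)
    v = valid.astype(float)
    if np.nanstd(rate_map.rates[valid]) == 0:
        shape = (2 * x.shape[0] - 1, 2 * x.shape[1] - 1)
        return Autocorrelogram(values=np.full(shape, np.nan),
                               bin_size=rate_map.bin_size, degenerate=True)
    n = _correlate_full(v, v)
    sx = _correlate_full(x, v)
    sy = _correlate_full(v, x)
    sxy = _correlate_full(x, x)
    sxx = _correlate_full(x * x, v)
    syy = _correlate_full(v, x * x)
    n = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt(np.maximum(n * sxx - sx**2, 0.0) *
                      np.maximum(n * syy - sy**2, 0.0))
        vals = np.where(den > 1e-12 * np.maximum(n, 1) * np.nanmax(x) ** 2 + 1e-300,
                        num / np.maximum(den, 1e-300), np.nan)
    vals[n < min_overlap] = np.nan
    vals = np.clip(vals, -1.0, 1.0)
    return Autocorrelogram(values=vals, bin_size=rate_map.bin_size)


def _annulus_correlation(a: np.ndarray, b: np.ndarray, sel: np.ndarray) -> float:
    x, y = a[sel], b[sel]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 10:
        return np.nan
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def gridness_score(
    acorr: Autocorrelogram,
    inner_radius: int | None = None,
    step: int = 1,
) -> float:
    """Hexagonality score of an autocorrelogram, in [-2, 2].

    The autocorrelogram is rotated in five 30-degree steps and correlated with
    the unrotated version within annuli whose inner edge sits just outside the
    masked center disk and whose outer edge expands stepwise (``step`` bins per
    expansion) to the edge of the matrix.  Each annulus scores
    min(r60, r120) - max(r30, r90, r150); the gridness is the mean of the best
    step and its two neighbors.  Degenerate inputs give NaN (flagged score).
    """
    if acorr.degenerate:
        return np.nan
    inner = acorr.center_mask_radius if inner_radius is None else inner_radius
    base = np.where(np.isfinite(acorr.values), acorr.values, 0.0)
    rad = acorr.radius_grid()
    max_rad = int(min(acorr.center))
    outer_radii = np.arange(inner + 2, max_rad + 1, step)
    if len(outer_radii) < 3:
        return np.nan
    rotations = {
        ang: nd_rotate(base, ang, reshape=False, order=1, mode="constant", cval=0.0)
        for ang in (30, 60, 90, 120, 150)
    }
    scores = np.full(len(outer_radii), np.nan)
    for k, outer in enumerate(outer_radii):
        sel = (rad > inner) & (rad <= outer)
        corrs = {ang: _annulus_correlation(base, rot, sel)
                 for ang, rot in rotations.items()}
        if any(not np.isfinite(c) for c in corrs.values()):
            continue
        scores[k] = min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150])
    if not np.isfinite(scores).any():
        return np.nan
    best = int(np.nanargmax(scores))
    lo, hi = max(0, best - 1), min(len(scores), best + 2)
    window = scores[lo:hi]
    return float(np.nanmean(window))


# ---------------------------------------------------------------------------
# spatial information
# ---------------------------------------------------------------------------

def spatial_information(rate_map: RateMap, occupancy: np.ndarray) -> float:
    """Spatial information content in bits per spike.

    I = sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda), with occupancy
    probabilities p_i over valid bins and lambda the occupancy-weighted mean
    rate; 0*log(0) is taken as 0.  Returns NaN (flagged) when the mean rate
    is zero.
    """
    v = rate_map.valid & (np.asarray(occupancy) > 0)
    if not v.any():
        return np.nan
    p = occupancy[v].astype(float)
    p = p / p.sum()
    lam = rate_map.rates[v]
    mean_rate = float(np.sum(p * lam))
    if mean_rate <= 0:
        return np.nan
    ratio = lam / mean_rate
    terms = np.where(ratio > 0, p * ratio * np.log2(np.maximum(ratio, 1e-300)), 0.0)
    return float(terms.sum())
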