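"""Synthetic foraging sessions: trajectories, idealized grid cells, spikes.

Stands in for recorded sessions: a rat foraging in a circular arena, with
populations of grid cells organized in modules.  Tuning curves are sums of
Gaussian blobs on a perfect hexagonal lattice (peak rate 30 Hz, blob variance
0.015·λ² cm² per dimension); spikes are inhomogeneous Poisson given the
trajectory.  Controlled departures from perfect inter-module coordination are
injected through per-module drift of the *encoded* position, which is the
ground-truth analog of uncoordinated attractor states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .arena import Arena

__all__ = [
    "Trajectory",
    "GridCellSpec",
    "SpikeData",
    "DriftSpec",
    "simulate_trajectory",
    "idealized_tuning_curve",
    "build_population",
    "generate_spikes",
    "rate_scale_condition",
]

DEFAULT_DT = 1.0 / 120.0  # tracking resolution, s
DEFAULT_PEAK_RATE = 30.0  # Hz
BLOB_VARIANCE_FACTOR = 0.015  # blob variance = 0.015 * spacing**2, cm^2


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-stamped 2-D positions (cm), uniformly sampled at ``dt`` seconds."""

    times: np.ndarray
    positions: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.times), 2):
            raise ValueError("positions must be (T, 2) matching times")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    def speed(self, smooth_window: float = 0.1) -> np.ndarray:
        """Speed (cm/s) by central differences, boxcar-smoothed.

        ``smooth_window`` is the boxcar width in seconds (default 100 ms);
        the raw central-difference estimate at 120 Hz is noisy, so the speed
        entering the 3-cm/s movement threshold is smoothed first.
        """
        pos = self.positions
        vel = np.gradient(pos, self.dt, axis=0)
        spd = np.hypot(vel[:, 0], vel[:, 1])
        w = max(1, int(round(smooth_window / self.dt)))
        if w > 1:
            spd = uniform_filter1d(spd, size=w, mode="nearest")
        return spd

    def moving_mask(self, speed_min: float = 3.0) -> np.ndarray:
        """Bins where the animal moves at >= ``speed_min`` cm/s."""
        return self.speed() >= speed_min


def simulate_trajectory(
    arena: Arena,
    duration: float,
    dt: float = DEFAULT_DT,
    speed_scale: float = 20.0,
    persistence_time: float = 1.0,
    start: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> Trajectory:
    """Smooth persistent random walk in the arena.

    The velocity follows an Ornstein-Uhlenbeck process with per-component
    stationary SD ``speed_scale`` (cm/s) and relaxation time
    ``persistence_time`` (s); the resulting speed is Rayleigh-distributed with
    median ``speed_scale * sqrt(2 ln 2)`` (≈19 cm/s at the default), in the
    range of foraging rodents.  Walls reflect (disk) or wrap (torus).

    Raises ``ValueError`` for non-positive duration or dt.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if speed_scale < 0 or persistence_time <= 0:
        raise ValueError("speed_scale must be >= 0 and persistence_time > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    pos = np.empty((n, 2))
    if start is None:
        if arena.topology == "torus":
            x = rng.uniform(0.0, arena.period, size=2)
        else:
            # uniform in the disk
            r = arena.radius * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            x = np.array([r * np.cos(th), r * np.sin(th)])
    else:
        x = np.asarray(start, dtype=float).copy()
    v = rng.normal(0.0, speed_scale, size=2)
    theta = dt / persistence_time
    noise_sd = speed_scale * np.sqrt(2.0 * theta) if speed_scale > 0 else 0.0
    pos[0] = x
    for t in range(1, n):
        v = v * (1.0 - theta) + rng.normal(0.0, 1.0, size=2) * noise_sd
        x = x + v * dt
        if arena.topology == "torus":
            x = np.mod(x, arena.period)
        else:
            rad = np.hypot(x[0], x[1])
            if rad > arena.radius:
                nvec = x / rad
                x = x - 2.0 * (rad - arena.radius) * nvec
                v = v - 2.0 * np.dot(v, nvec) * nvec
                rad = np.hypot(x[0], x[1])
                if rad > arena.radius:  # pathological double-crossing; clamp
                    x = x * (arena.radius / rad)
        pos[t] = x
    times = np.arange(n) * dt
    return Trajectory(times=times, positions=pos, dt=dt)


# ---------------------------------------------------------------------------
# idealized grid cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridCellSpec:
    """An idealized grid cell: hexagonal lattice of Gaussian firing fields.

    ``phase`` is the 2-D offset of one lattice node from the origin, reduced
    modulo the lattice; ``blob_variance`` is the per-dimension variance of
    each Gaussian blob (0.015·spacing² unless overridden).
    """

    module_id: int
    spacing: float
    orientation: float
    phase: tuple[float, float] = (0.0, 0.0)
    peak_rate: float = DEFAULT_PEAK_RATE
    blob_variance: float | None = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be positive")
        if self.blob_variance is None:
            object.__setattr__(
                self, "blob_variance", BLOB_VARIANCE_FACTOR * self.spacing**2
            )
        # reduce the phase modulo the lattice
        basis = self.lattice_basis()
        frac = np.linalg.solve(basis, np.asarray(self.phase, dtype=float))
        frac -= np.floor(frac)
        reduced = basis @ frac
        object.__setattr__(self, "phase", (float(reduced[0]), float(reduced[1])))

    def lattice_basis(self) -> np.ndarray:
        """Columns are the two primitive lattice vectors (60 deg apart)."""
        a0 = self.orientation
        a1 = self.orientation + np.pi / 3.0
        return self.spacing * np.array(
            [[np.cos(a0), np.cos(a1)], [np.sin(a0), np.sin(a1)]]
        )


def idealized_tuning_curve(
    spec: GridCellSpec,
    at: np.ndarray,
    arena: Arena | None = None,
) -> np.ndarray:
    """Firing rate (Hz) of an idealized grid cell at the given positions.

    The rate is a sum of Gaussian blobs centered on the hexagonal lattice
    nodes.  Blobs are narrow relative to the spacing (SD ≈ 0.12·λ), so only
    the nodes of the unit cell surrounding each position contribute above
    machine precision; the sum runs over that 4x4 node neighborhood, which
    is exact to ~1e-15 relative error.

    In torus arenas the positions are wrapped before evaluation, which makes
    the realized field exactly periodic under arena wrapping.
    """
    at = np.atleast_2d(np.asarray(at, dtype=float))
    if arena is not None:
        at = arena.wrap(at)
    basis = spec.lattice_basis()
    inv = np.linalg.inv(basis)
    rel = at - np.asarray(spec.phase)
    frac = rel @ inv.T
    base = np.floor(frac)
    if spec.blob_variance <= (0.15 * spec.spacing) ** 2:
        # narrow blobs: only the 4 surrounding-cell corners contribute
        offs = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    else:
        offs = np.array([[i, j] for i in (-1, 0, 1, 2) for j in (-1, 0, 1, 2)],
                        dtype=float)
    # node positions for every (position, offset) pair
    nodes = (base[:, None, :] + offs[None, :, :]) @ basis.T
    d2 = np.sum((rel[:, None, :] - nodes) ** 2, axis=-1)
    rates = spec.peak_rate * np.exp(-0.5 * d2 / spec.blob_variance).sum(axis=1)
    return rates


def build_population(
    spacings: list[float],
    counts_per_module: list[int],
    seed: int | np.random.Generator | None = None,
    peak_rate: float = DEFAULT_PEAK_RATE,
) -> list[GridCellSpec]:
    """Idealized multi-module population.

    Within a module all cells share spacing and orientation; phases are
    uniform on the unit cell; module orientations are independent uniform
    draws (orientation matters only modulo 60 deg by hexagonal symmetry).
    """
    if len(spacings) != len(counts_per_module):
        raise ValueError("spacings and counts_per_module must have equal length")
    if any(c < 1 for c in counts_per_module):
        raise ValueError("counts_per_module entries must be >= 1")
    rng = np.random.default_rng(seed)
    specs: list[GridCellSpec] = []
    for m, (lam, count) in enumerate(zip(spacings, counts_per_module)):
        orientation = rng.uniform(0.0, np.pi / 3.0)
        tmp = GridCellSpec(module_id=m, spacing=lam, orientation=orientation,
                           peak_rate=peak_rate)
        basis = tmp.lattice_basis()
        for _ in range(count):
            frac = rng.uniform(0.0, 1.0, size=2)
            phase = basis @ frac
            specs.append(
                GridCellSpec(
                    module_id=m,
                    spacing=lam,
                    orientation=orientation,
                    phase=(phase[0], phase[1]),
                    peak_rate=peak_rate,
                )
            )
    return specs


# ---------------------------------------------------------------------------
# spikes and drift
# ---------------------------------------------------------------------------

@dataclass
class DriftSpec:
    """Per-module 2-D offset applied to the encoded position, per time bin.

    ``offsets`` has shape (n_modules, T, 2) in cm.  Zero offsets mean every
    module encodes the true trajectory (perfect coordination); identical
    nonzero offsets across modules model a coordinated internal drift;
    independent offsets model uncoordinated modules.
    """

    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 3 or self.offsets.shape[-1] != 2:
            raise ValueError("offsets must have shape (n_modules, T, 2)")

    @classmethod
    def zero(cls, n_modules: int, n_steps: int) -> "DriftSpec":
        return cls(np.zeros((n_modules, n_steps, 2)))

    @classmethod
    def constant(cls, offsets: np.ndarray, n_steps: int) -> "DriftSpec":
        """Fixed per-module offsets, shape (n_modules, 2)."""
        offsets = np.asarray(offsets, dtype=float)
        return cls(np.repeat(offsets[:, None, :], n_steps, axis=1))

    @classmethod
    def random_walk(
        cls,
        n_modules: int,
        n_steps: int,
        final_sd: float,
        seed: int | np.random.Generator | None = None,
        shared: bool = False,
    ) -> "DriftSpec":
        """Brownian drift with per-axis SD ``final_sd`` cm at the last bin.

        ``shared=True`` uses one walk for all modules (coordinated drift);
        otherwise walks are independent per module (uncoordinated drift).
        """
        rng = np.random.default_rng(seed)
        step_sd = final_sd / np.sqrt(n_steps)
        n_walks = 1 if shared else n_modules
        steps = rng.normal(0.0, step_sd, size=(n_walks, n_steps, 2))
        walks = np.cumsum(steps, axis=1)
        if shared:
            walks = np.repeat(walks, n_modules, axis=0)
        return cls(walks)


@dataclass
class SpikeData:
    """Binned spike counts for a population, aligned to a trajectory clock."""

    counts: np.ndarray  # (N, T), non-negative ints
    module_labels: np.ndarray  # (N,)
    dt: float
    specs: list[GridCellSpec] | None = None
    unit_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.module_labels = np.asarray(self.module_labels)
        if self.counts.ndim != 2:
            raise ValueError("counts must be (N, T)")
        if len(self.module_labels) != self.counts.shape[0]:
            raise ValueError("module_labels length must match counts rows")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.counts.shape[0])

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def mean_rates(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-neuron mean firing rate (Hz), optionally over masked bins."""
        c = self.counts if mask is None else self.counts[:, mask]
        if c.shape[1] == 0:
            return np.zeros(self.n_neurons)
        return c.mean(axis=1) / self.dt

    def module_indices(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.module_labels == module)


def generate_spikes(
    specs: list[GridCellSpec],
    trajectory: Trajectory,
    drift: DriftSpec | None = None,
    seed: int | np.random.Generator | None = None,
    arena: Arena | None = None,
) -> SpikeData:
    """Inhomogeneous Poisson spikes from idealized tuning curves.

    Per-bin counts are Poisson with mean ``f_i(x_t + drift_m(t)) * dt``,
    independent across neurons given the trajectory.  Drift moves the
    *encoded* position of each module; with zero drift all modules encode the
    true trajectory exactly.
    """
    rng = np.random.default_rng(seed)
    T = len(trajectory)
    labels = np.array([s.module_id for s in specs])
    if drift is None:
        drift = DriftSpec.zero(int(labels.max()) + 1 if len(labels) else 0, T)
    if drift.offsets.shape[1] != T:
        raise ValueError("drift offsets must have one entry per trajectory bin")
    counts = np.empty((len(specs), T), dtype=np.int32)
    module_pos: dict[int, np.ndarray] = {}
    for m in np.unique(labels):
        module_pos[int(m)] = trajectory.positions + drift.offsets[int(m)]
    for i, spec in enumerate(specs):
        rates = idealized_tuning_curve(spec, module_pos[spec.module_id], arena=arena)
        if np.any(rates < 0):
            raise ValueError("negative firing rate encountered")
        counts[i] = rng.poisson(rates * trajectory.dt)
    return SpikeData(counts=counts, module_labels=labels, dt=trajectory.dt,
                     specs=list(specs))


def generate_spikes_from_rates(
    rates: np.ndarray,
    dt: float,
    module_labels: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> SpikeData:
    """Poisson spikes from a user-supplied (N, T) rate array (Hz)."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("negative firing rate encountered")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates * dt).astype(np.int32)
    return SpikeData(counts=counts, module_labels=np.asarray(module_labels), dt=dt)


def rate_scale_condition(
    spikes: SpikeData,
    factor: float | np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> SpikeData:
    """Binomial thinning of spike counts, emulating rate reduction in darkness.

    Each spike is kept independently with probability ``factor`` (scalar or
    per-neuron, in (0, 1]); the expected mean rate scales by ``factor`` while
    the bin structure is unchanged.
    """
    factor = np.asarray(factor, dtype=float)
    if np.any(factor <= 0) or np.any(factor > 1):
        raise ValueError("thinning factor must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    p = np.broadcast_to(factor.reshape(-1, 1) if factor.ndim else factor,
                        spikes.counts.shape)
    new_counts = rng.binomial(spikes.counts, p).astype(spikes.counts.dtype)
    return replace(spikes, counts=new_counts)
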