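"""Arena geometry and the spatial bin grids shared by all analyses.

The recording environment is a circular open-field arena (the study conditions
use a 150-cm-diameter disk).  A periodic (torus) variant is provided as a
boundary-free control: identical-shift perturbations are exact symmetries on
the torus, so any residual likelihood change on the disk can be attributed to
wall effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Arena", "BinGrid"]


@dataclass(frozen=True)
class Arena:
    """Circular (disk) or periodic (torus) arena.

    Parameters
    ----------
    radius
        Arena radius in cm (default 75, i.e. a 150-cm-diameter disk).
    topology
        ``"disk"``: positions satisfy ``|x| <= radius``, origin at the center.
        ``"torus"``: both coordinates wrap on ``[0, 2*radius)``; there are no
        walls, so boundary effects vanish.
    """

    radius: float = 75.0
    topology: str = "disk"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("arena radius must be positive")
        if self.topology not in ("disk", "torus"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def period(self) -> float:
        """Wrap length of the torus (only meaningful for torus topology)."""
        return 2.0 * self.radius

    def contains(self, positions: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Boolean mask of positions inside the arena (always True on a torus)."""
        positions = np.asarray(positions, dtype=float)
        if self.topology == "torus":
            return np.ones(positions.shape[:-1], dtype=bool)
        return np.hypot(positions[..., 0], positions[..., 1]) <= self.radius + atol

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap positions into the fundamental domain (no-op on a disk)."""
        positions = np.asarray(positions, dtype=float)
        if self.topology == "torus":
            return np.mod(positions, self.period)
        return positions


@dataclass(frozen=True)
class BinGrid:
    """Square discretization of an arena, with a validity mask.

    Bins are ``bin_size`` cm squares; a bin is valid if its center lies inside
    the arena.  ``centers`` holds the valid bin centers as an ``(B, 2)`` array;
    2-D fields are stored either densely (``shape``, with invalid bins masked)
    or flattened over valid bins only.
    """

    arena: Arena
    bin_size: float
    edges_x: np.ndarray = field(repr=False)
    edges_y: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)

    @classmethod
    def for_arena(cls, arena: Arena, bin_size: float) -> "BinGrid":
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if arena.topology == "torus":
            n = int(np.ceil(arena.period / bin_size))
            edges = np.linspace(0.0, arena.period, n + 1)
            edges_x = edges_y = edges
            bin_size = arena.period / n  # realized size; divides the period
        else:
            n = int(np.ceil(2.0 * arena.radius / bin_size))
            half = n * bin_size / 2.0
            edges_x = edges_y = np.linspace(-half, half, n + 1)
        cx = 0.5 * (edges_x[:-1] + edges_x[1:])
        cy = 0.5 * (edges_y[:-1] + edges_y[1:])
        gx, gy = np.meshgrid(cx, cy, indexing="xy")
        centers = np.stack([gx.ravel(), gy.ravel()], axis=-1)
        mask = arena.contains(centers).reshape(gy.shape)
        return cls(arena=arena, bin_size=float(bin_size),
                   edges_x=edges_x, edges_y=edges_y, mask=mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def centers_xy(self) -> tuple[np.ndarray, np.ndarray]:
        cx = 0.5 * (self.edges_x[:-1] + self.edges_x[1:])
        cy = 0.5 * (self.edges_y[:-1] + self.edges_y[1:])
        return cx, cy

    @property
    def all_centers(self) -> np.ndarray:
        """Centers of every bin (valid or not), shape (rows*cols, 2)."""
        cx, cy = self.centers_xy
        gx, gy = np.meshgrid(cx, cy, indexing="xy")
        return np.stack([gx.ravel(), gy.ravel()], axis=-1)

    @property
    def centers(self) -> np.ndarray:
        """Centers of the valid bins only, shape (B, 2)."""
        return self.all_centers[self.mask.ravel()]

    def to_dense(self, flat: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Expand values over valid bins to a dense (rows, cols) array."""
        flat = np.asarray(flat)
        out = np.full(flat.shape[:-1] + self.mask.shape, fill, dtype=float)
        out[..., self.mask] = flat
        return out

    def position_to_index(self, positions: np.ndarray) -> np.ndarray:
        """Row/column indices of the bins containing each position."""
        positions = self.arena.wrap(np.asarray(positions, dtype=float))
        ix = np.clip(np.searchsorted(self.edges_x, positions[..., 0], side="right") - 1,
                     0, len(self.edges_x) - 2)
        iy = np.clip(np.searchsorted(self.edges_y, positions[..., 1], side="right") - 1,
                     0, len(self.edges_y) - 2)
        return np.stack([iy, ix], axis=-1)
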