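"""Shared synthetic-session fixtures.

The base session mirrors the study conditions: a 150-cm-diameter disk arena,
three grid modules with spacings [45, 65, 95] cm and 41/74/90 cells (the
largest recorded-session allocation), 30-Hz peak rates, 120-Hz tracking.
Durations are kept short (2 min) so the full suite stays fast; the decoders
reach centimeter accuracy well within that.
"""

import numpy as np
import pytest

from gridcoord import (
    Arena,
    BinGrid,
    build_population,
    generate_spikes,
    simulate_trajectory,
)
from gridcoord.maps import rate_matrix_from_specs

SPACINGS = [45.0, 65.0, 95.0]
COUNTS = [41, 74, 90]
SESSION_DURATION = 120.0  # s
RATE_FLOOR = 1e-3


@pytest.fixture(scope="session")
def arena_disk():
    return Arena(radius=75.0, topology="disk")


@pytest.fixture(scope="session")
def grid3(arena_disk):
    return BinGrid.for_arena(arena_disk, 3.0)


@pytest.fixture(scope="session")
def base_session(arena_disk, grid3):
    """Coordinated (zero-drift) multi-module session plus decode inputs."""
    traj = simulate_trajectory(arena_disk, SESSION_DURATION, seed=11)
    specs = build_population(SPACINGS, COUNTS, seed=12)
    spikes = generate_spikes(specs, traj, seed=13, arena=arena_disk)
    rates = rate_matrix_from_specs(specs, grid3, floor=RATE_FLOOR)
    return {
        "arena": arena_disk,
        "grid": grid3,
        "trajectory": traj,
        "specs": specs,
        "spikes": spikes,
        "rates": rates,
        "moving": traj.moving_mask(),
        "spacings": {s.module_id: s.spacing for s in specs},
        "module_ids": sorted({s.module_id for s in specs}),
    }


@pytest.fixture(scope="session")
def torus_session():
    """Boundary-free control session on a periodic arena."""
    arena = Arena(radius=75.0, topology="torus")
    grid = BinGrid.for_arena(arena, 3.0)
    traj = simulate_trajectory(arena, SESSION_DURATION, seed=21)
    specs = build_population(SPACINGS, COUNTS, seed=22)
    spikes = generate_spikes(specs, traj, seed=23, arena=arena)
    rates = rate_matrix_from_specs(specs, grid, floor=RATE_FLOOR)
    return {
        "arena": arena,
        "grid": grid,
        "trajectory": traj,
        "specs": specs,
        "spikes": spikes,
        "rates": rates,
        "moving": traj.moving_mask(),
        "module_ids": sorted({s.module_id for s in specs}),
    }
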