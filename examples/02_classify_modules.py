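"""Classify cells into grid modules from their autocorrelogram features.

Estimates classification rate maps (9-cm bins) for three idealized modules
plus spatially untuned cells, embeds the masked autocorrelograms with UMAP,
clusters with DBSCAN, and validates the clustering with the DBCV index.
"""

import numpy as np

from gridcoord import (
    Arena,
    BinGrid,
    build_features,
    build_population,
    compute_rate_map,
    embed_and_cluster,
    generate_spikes,
    simulate_trajectory,
)
from gridcoord.synthetic import generate_spikes_from_rates

arena = Arena()
trajectory = simulate_trajectory(arena, 240.0, seed=1)
specs = build_population([45.0, 65.0, 95.0], [25, 25, 25], seed=2)
grid_cells = generate_spikes(specs, trajectory, seed=3, arena=arena)
untuned = generate_spikes_from_rates(
    np.full((25, len(trajectory)), 5.0), trajectory.dt, np.full(25, -1), seed=4)
counts = np.vstack([grid_cells.counts, untuned.counts])

grid = BinGrid.for_arena(arena, 9.0)
maps = [compute_rate_map(counts[i], trajectory, grid)
        for i in range(len(counts))]
assignment = embed_and_cluster(build_features(maps), seed=0)

cols = ["label", "n_cells", "mean_gridness", "spacing_cm", "is_grid"]
print(assignment.clusters[cols].to_string(index=False))
print(f"\nDBCV validity index: {assignment.dbcv_with_noise:.2f} "
      f"(excluding non-grid cluster: {assignment.dbcv_without_noise:.2f})")
print()
print("Three clusters with mean gridness of order 1 are grid modules whose")
print("spacings recover the generating 45/65/95 cm; the low-gridness cluster")
print("collects the untuned cells.  A DBCV index near 1 marks clean,")
print("density-separated clusters.")
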