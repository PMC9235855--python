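"""Shift sweep: the marginalized likelihood detects inter-module incoherence.

Applies decode-time spatial shifts to the rate maps — independently per
module (destroying inter-module coherence) or identically for all modules
(preserving it) — and tracks the average log likelihood L and the decoding
error.  Independent shifts lower L sharply; identical shifts barely touch it
even though the decoding error grows just as much.
"""

import numpy as np

from gridcoord import (
    Arena,
    BinGrid,
    avg_log_likelihood,
    build_population,
    decode_markov,
    draw_shifts,
    generate_spikes,
    mae,
    shift_rate_maps,
    simulate_trajectory,
)
from gridcoord.maps import rate_matrix_from_specs

arena = Arena()
grid = BinGrid.for_arena(arena, 3.0)
trajectory = simulate_trajectory(arena, 120.0, seed=1)
specs = build_population([45.0, 65.0, 95.0], [41, 74, 90], seed=2)
spikes = generate_spikes(specs, trajectory, seed=3, arena=arena)
rates = rate_matrix_from_specs(specs, grid, floor=1e-3)
moving = trajectory.moving_mask()
module_ids = sorted({s.module_id for s in specs})

print(f"{'mode':12s} {'alpha':>5s} {'L':>9s} {'MAE (cm)':>9s}")
for mode in ("independent", "identical"):
    for alpha in (0.0, 10.0, 20.0):
        stack = []
        for k in range(4):  # average over 4 shift draws
            shift = draw_shifts(module_ids, mode, "translate", alpha,
                                seed=100 * int(alpha) + k)
            stack.append(np.maximum(
                shift_rate_maps(rates, spikes.module_labels, grid, shift,
                                specs=specs), 1e-3))
        res = decode_markov(spikes, np.stack(stack), grid)
        Ls, errs = [], []
        for r in range(len(stack)):
            rr = res.realization(r)
            Ls.append(avg_log_likelihood(rr, moving)[0])
            errs.append(mae(rr.mle_positions, trajectory.positions, moving)[0])
        print(f"{mode:12s} {alpha:5.0f} {np.mean(Ls):9.3f} {np.mean(errs):9.2f}")

print()
print("Reading the table: at alpha=20 cm, independent shifts cost several")
print("nats of likelihood per bin while identical shifts cost almost none —")
print("yet both inflate the MAE.  L therefore isolates inter-module")
print("coherence from mere misalignment with the true position.")
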