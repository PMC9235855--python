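"""Reproducible end-to-end runs: config, seeding, and stage orchestration.

A :class:`SessionConfig` pins every knob of a simulated-session analysis —
arena, population, trajectory statistics, decoder parameters, and the
perturbation sweep grid — together with one master seed from which all
per-stage seeds are derived.  ``run_pipeline`` executes
simulate -> decode (both decoders) -> nulls (-> optional sweep) and returns a
result bundle stamped with the config hash, so identical configs produce
identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .arena import Arena, BinGrid
from .kernel import coordination_distances, decode_kernel
from .markov import TransitionModel, avg_log_likelihood, decode_markov
from .maps import DECODING_BIN, RATE_FLOOR, rate_matrix_from_specs
from .perturb import shift_rate_maps, sweep as run_sweep
from .stats import mae, null_delta, null_mae
from .synthetic import (
    DriftSpec,
    build_population,
    generate_spikes,
    simulate_trajectory,
)

__all__ = ["SessionConfig", "run_pipeline"]


@dataclass
class SessionConfig:
    """All parameters of one synthetic-session analysis run."""

    arena_radius: float = 75.0
    arena_topology: str = "disk"
    duration: float = 600.0  # s
    dt: float = 1.0 / 120.0
    spacings: tuple[float, ...] = (45.0, 65.0, 95.0)
    counts_per_module: tuple[int, ...] = (41, 74, 90)
    peak_rate: float = 30.0
    speed_min: float = 3.0  # cm/s movement threshold
    decoding_bin: float = DECODING_BIN
    step_variance: float = 4.0  # cm^2, Markov transition
    tau: float = 0.1  # s, kernel decoder
    rate_floor: float = RATE_FLOOR
    burn_in: float = 5.0  # s excluded from L
    area_frac: float = 0.9
    kernel_stride: int = 4
    sweep_alphas: tuple[float, ...] = ()
    sweep_mode: str = "independent"
    sweep_realizations: int = 10
    drift_final_sd: float = 0.0  # cm; >0 injects per-module random-walk drift
    drift_shared: bool = False
    condition_label: str = "light-like"
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SessionConfig":
        data = yaml.safe_load(text)
        for key in ("spacings", "counts_per_module", "sweep_alphas"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: SessionConfig) -> dict:
    """Execute a full simulated-session analysis.

    Stages: simulate trajectory and spikes, decode with the Markov and kernel
    decoders, compute null values, and (when ``sweep_alphas`` is non-empty)
    run the decode-time shift sweep.  A stage failure raises with the stage
    name; results computed so far are attached to the exception.
    """
    bundle: dict = {"config": config, "config_hash": config.config_hash}
    stage = "simulate"
    try:
        arena = Arena(radius=config.arena_radius, topology=config.arena_topology)
        trajectory = simulate_trajectory(
            arena, config.duration, config.dt, seed=config.stage_seed("trajectory"))
        specs = build_population(
            list(config.spacings), list(config.counts_per_module),
            seed=config.stage_seed("population"), peak_rate=config.peak_rate)
        n_mod = len(config.spacings)
        if config.drift_final_sd > 0:
            drift = DriftSpec.random_walk(
                n_mod, len(trajectory), config.drift_final_sd,
                seed=config.stage_seed("drift"), shared=config.drift_shared)
        else:
            drift = DriftSpec.zero(n_mod, len(trajectory))
        spikes = generate_spikes(specs, trajectory, drift=drift,
                                 seed=config.stage_seed("spikes"), arena=arena)
        grid = BinGrid.for_arena(arena, config.decoding_bin)
        rates = rate_matrix_from_specs(specs, grid, floor=config.rate_floor)
        moving = trajectory.moving_mask(config.speed_min)
        bundle.update(arena=arena, trajectory=trajectory, specs=specs,
                      spikes=spikes, grid=grid, rates=rates, moving=moving)

        stage = "decode-markov"
        transition = TransitionModel(step_variance=config.step_variance)
        mres = decode_markov(spikes, rates, grid, transition,
                             rate_floor=config.rate_floor)
        L, L_sem = avg_log_likelihood(mres, moving, burn_in=config.burn_in)
        m_mae, m_mae_sem = mae(mres.mle_positions, trajectory.positions, moving)
        bundle["markov"] = {"result": mres, "L": L, "L_sem": L_sem,
                            "mae_cm": m_mae, "mae_sem_cm": m_mae_sem}

        stage = "decode-kernel"
        kest = decode_kernel(spikes, rates, grid, tau=config.tau,
                             area_frac=config.area_frac,
                             stride=config.kernel_stride,
                             rate_floor=config.rate_floor)
        kmoving = moving[::config.kernel_stride]
        coord = coordination_distances(kest, kmoving)
        k_mae, k_mae_sem = mae(kest.m_hat,
                               trajectory.positions[::config.kernel_stride],
                               kmoving)
        bundle["kernel"] = {"estimates": kest, "coordination": coord,
                            "mae_cm": k_mae, "mae_sem_cm": k_mae_sem}

        stage = "nulls"
        nm, nm_sem = null_mae(trajectory, arena, seed=config.stage_seed("nullmae"),
                              mask=moving)
        bundle["nulls"] = {
            "mae_cm": nm, "mae_sem_cm": nm_sem,
            "delta": null_delta(np.asarray(config.spacings), config.area_frac,
                                seed=config.stage_seed("nulldelta")),
        }

        if config.sweep_alphas:
            stage = "sweep"
            labels = spikes.module_labels

            def run_one(shift_spec):
                shifted = shift_rate_maps(rates, labels, grid, shift_spec,
                                          specs=specs)
                shifted = np.maximum(shifted, config.rate_floor)
                res = decode_markov(spikes, shifted, grid, transition,
                                    rate_floor=config.rate_floor)
                Ls, Ls_sem = avg_log_likelihood(res, moving,
                                                burn_in=config.burn_in)
                e, e_sem = mae(res.mle_positions, trajectory.positions, moving)
                return {"L": Ls, "L_sem": Ls_sem, "mae_cm": e,
                        "mae_sem_cm": e_sem}

            bundle["sweep"] = run_sweep(
                list(config.sweep_alphas), config.sweep_realizations, run_one,
                module_ids=sorted(set(int(m) for m in labels)),
                mode=config.sweep_mode, kind="translate",
                seed=config.stage_seed("sweep"))
    except Exception as exc:
        exc.add_note(f"pipeline stage failed: {stage}")
        exc.partial_bundle = bundle  # type: ignore[attr-defined]
        raise
    return bundle
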