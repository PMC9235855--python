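import numpy as np
import pytest
from scipy import stats as sps

from gridcoord import (
    Arena,
    DriftSpec,
    GridCellSpec,
    build_population,
    generate_spikes,
    idealized_tuning_curve,
    rate_scale_condition,
    simulate_trajectory,
)
from gridcoord.maps import occupancy_map
from gridcoord.arena import BinGrid
from gridcoord.synthetic import generate_spikes_from_rates


class TestTrajectory:
    def test_containment_and_length(self):
        arena = Arena(radius=75.0)
        traj = simulate_trajectory(arena, 60.0, dt=1 / 120, seed=0)
        assert len(traj) == 7200
        assert arena.contains(traj.positions).all()

    def test_zero_speed_stays_at_start(self):
        arena = Arena(radius=75.0)
        traj = simulate_trajectory(arena, 2.0, speed_scale=0.0,
                                   start=np.array([10.0, -5.0]), seed=0)
        assert np.allclose(traj.positions, [10.0, -5.0])

    @pytest.mark.parametrize("kwargs", [{"duration": -1.0}, {"duration": 10.0, "dt": 0.0}])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_trajectory(Arena(), **{"dt": 1 / 120, **kwargs})

    def test_speed_statistics_in_foraging_range(self):
        traj = simulate_trajectory(Arena(), 300.0, seed=1)
        med = np.median(traj.speed())
        assert 15.0 <= med <= 25.0
        assert traj.moving_mask().mean() > 0.9

    def test_uniform_coverage_pair_distance(self):
        # mean distance between two independent positions on a long run
        # approaches the uniform-disk closed form 128 R / (45 pi) ~= 67.9 cm
        traj = simulate_trajectory(Arena(), 1800.0, seed=7)
        rng = np.random.default_rng(0)
        i = rng.integers(0, len(traj), 30000)
        j = rng.integers(0, len(traj), 30000)
        d = np.hypot(*(traj.positions[i] - traj.positions[j]).T).mean()
        assert abs(d - 128 * 75 / (45 * np.pi)) < 1.5

    def test_long_run_occupancy_near_uniform(self):
        # the occupancy CV decays with duration toward the sampling floor;
        # a 90-min run is comfortably below 0.2
        traj = simulate_trajectory(Arena(), 5400.0, seed=3)
        grid = BinGrid.for_arena(Arena(), 10.0)
        occ = occupancy_map(traj, grid)[grid.mask]
        assert occ.std() / occ.mean() < 0.2


class TestTuningCurves:
    def test_peak_rate_at_lattice_node(self):
        spec = GridCellSpec(module_id=0, spacing=65.0, orientation=0.3,
                            phase=(5.0, 7.0))
        rate = idealized_tuning_curve(spec, np.asarray(spec.phase)[None])[0]
        assert np.isclose(rate, 30.0, atol=1e-6)

    def test_blob_variance_scaling(self):
        spec = GridCellSpec(module_id=0, spacing=45.0, orientation=0.0)
        assert np.isclose(spec.blob_variance, 0.015 * 45.0**2)

    def test_lattice_periodicity(self):
        spec = GridCellSpec(module_id=0, spacing=65.0, orientation=1.1,
                            phase=(3.0, -4.0))
        pts = np.random.default_rng(0).uniform(-60, 60, (200, 2))
        shift = spec.lattice_basis() @ np.array([2.0, -1.0])
        r0 = idealized_tuning_curve(spec, pts)
        r1 = idealized_tuning_curve(spec, pts + shift)
        assert np.allclose(r0, r1, rtol=1e-9, atol=1e-9)

    def test_phase_differing_by_lattice_vector_identical(self):
        base = GridCellSpec(module_id=0, spacing=45.0, orientation=0.7,
                            phase=(2.0, 3.0))
        shifted_phase = np.asarray(base.phase) + base.lattice_basis() @ [1, 1]
        other = GridCellSpec(module_id=0, spacing=45.0, orientation=0.7,
                             phase=tuple(shifted_phase))
        pts = np.random.default_rng(1).uniform(-75, 75, (100, 2))
        assert np.allclose(idealized_tuning_curve(base, pts),
                           idealized_tuning_curve(other, pts))

    def test_torus_mode_exactly_periodic(self):
        arena = Arena(radius=75.0, topology="torus")
        spec = GridCellSpec(module_id=0, spacing=65.0, orientation=0.4,
                            phase=(10.0, 20.0))
        pts = np.random.default_rng(2).uniform(0, 150, (100, 2))
        r0 = idealized_tuning_curve(spec, pts, arena=arena)
        r1 = idealized_tuning_curve(spec, pts + [arena.period, 0.0], arena=arena)
        r2 = idealized_tuning_curve(spec, pts + [0.0, -arena.period], arena=arena)
        # wrap-then-evaluate is periodic by construction; the only deviation
        # is float round-off in (x + period) mod period
        assert np.allclose(r0, r1, rtol=1e-9, atol=1e-12)
        assert np.allclose(r0, r2, rtol=1e-9, atol=1e-12)

    def test_rates_non_negative(self):
        spec = GridCellSpec(module_id=0, spacing=95.0, orientation=0.2)
        pts = np.random.default_rng(3).uniform(-80, 80, (500, 2))
        assert (idealized_tuning_curve(spec, pts) >= 0).all()


class TestPopulation:
    def test_session_scale_population(self):
        specs = build_population([45, 65, 95], [41, 74, 90], seed=0)
        assert len(specs) == 205
        assert len({s.module_id for s in specs}) == 3
        for m in range(3):
            mod = [s for s in specs if s.module_id == m]
            assert len({s.spacing for s in mod}) == 1
            assert len({s.orientation for s in mod}) == 1

    def test_single_cell_population_valid(self):
        specs = build_population([65.0], [1], seed=0)
        assert len(specs) == 1

    def test_deterministic_under_seed(self):
        a = build_population([45, 65], [5, 5], seed=42)
        b = build_population([45, 65], [5, 5], seed=42)
        assert all(sa == sb for sa, sb in zip(a, b))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_population([45, 65], [10], seed=0)

    def test_phases_cover_unit_cell(self):
        specs = build_population([65.0], [300], seed=5)
        basis = specs[0].lattice_basis()
        fracs = np.array([np.linalg.solve(basis, s.phase) for s in specs])
        assert (fracs >= -1e-9).all() and (fracs < 1 + 1e-9).all()
        # both fractional coordinates roughly uniform
        for k in range(2):
            assert sps.kstest(fracs[:, k], "uniform").pvalue > 1e-3


class TestSpikes:
    def test_zero_rates_give_zero_spikes(self):
        spikes = generate_spikes_from_rates(np.zeros((3, 1000)), 1 / 120,
                                            np.zeros(3), seed=0)
        assert spikes.counts.sum() == 0

    def test_constant_rate_total_count_in_poisson_interval(self):
        # 30 Hz for 100 s: total count within the 99% Poisson interval of 3000
        rates = np.full((1, 12000), 30.0)
        spikes = generate_spikes_from_rates(rates, 1 / 120, [0], seed=1)
        lo, hi = sps.poisson.ppf([0.005, 0.995], 3000)
        assert lo <= spikes.counts.sum() <= hi

    def test_per_bin_counts_match_poisson_law(self):
        # chi-square goodness of fit of per-bin counts vs Poisson pmf
        rate, dt, n = 25.0, 1 / 120, 240000
        spikes = generate_spikes_from_rates(np.full((1, n), rate), dt, [0], seed=2)
        counts = spikes.counts[0]
        mu = rate * dt
        kmax = 3
        obs = np.array([(counts == k).sum() for k in range(kmax)] +
                       [(counts >= kmax).sum()])
        pk = sps.poisson.pmf(np.arange(kmax), mu)
        expected = np.concatenate([pk, [1 - pk.sum()]]) * n
        stat = ((obs - expected) ** 2 / expected).sum()
        assert stat < sps.chi2.ppf(0.99, df=kmax)

    def test_index_of_dispersion_near_one(self):
        spikes = generate_spikes_from_rates(np.full((1, 120000), 20.0), 1 / 120,
                                            [0], seed=3)
        c = spikes.counts[0]
        assert abs(c.var() / c.mean() - 1.0) < 0.02

    def test_zero_drift_equals_no_drift(self):
        arena = Arena()
        traj = simulate_trajectory(arena, 5.0, seed=4)
        specs = build_population([65.0], [3], seed=5)
        a = generate_spikes(specs, traj, seed=6, arena=arena)
        b = generate_spikes(specs, traj,
                            drift=DriftSpec.zero(1, len(traj)), seed=6,
                            arena=arena)
        assert np.array_equal(a.counts, b.counts)

    def test_drift_shifts_encoded_position(self):
        # constant drift equals evaluating the tuning curve at shifted positions
        arena = Arena()
        traj = simulate_trajectory(arena, 5.0, seed=7)
        specs = build_population([65.0], [2], seed=8)
        off = np.array([[12.0, -7.0]])
        drift = DriftSpec.constant(off, len(traj))
        a = generate_spikes(specs, traj, drift=drift, seed=9, arena=arena)
        shifted = traj.positions + off[0]
        expect0 = idealized_tuning_curve(specs[0], shifted, arena=arena)
        got = a.counts[0]
        # counts where the shifted rate is zero must be zero
        assert got[expect0 < 1e-12].sum() == 0

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            generate_spikes_from_rates(np.array([[-1.0]]), 1 / 120, [0])


class TestRateScaling:
    def test_factor_one_is_identity(self, base_session):
        spikes = base_session["spikes"]
        out = rate_scale_condition(spikes, 1.0, seed=0)
        assert np.array_equal(out.counts, spikes.counts)

    def test_half_factor_halves_rate(self):
        spikes = generate_spikes_from_rates(np.full((1, 120000), 20.0), 1 / 120,
                                            [0], seed=1)
        out = rate_scale_condition(spikes, 0.5, seed=2)
        total = spikes.counts.sum()
        got = out.counts.sum()
        sd = np.sqrt(total * 0.25)
        assert abs(got - 0.5 * total) < 4 * sd
        assert (out.counts <= spikes.counts).all()  # thinning only removes

    def test_deterministic_under_seed(self, base_session):
        spikes = base_session["spikes"]
        a = rate_scale_condition(spikes, 0.5, seed=3)
        b = rate_scale_condition(spikes, 0.5, seed=3)
        assert np.array_equal(a.counts, b.counts)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_factor_rejected(self, base_session, bad):
        with pytest.raises(ValueError):
            rate_scale_condition(base_session["spikes"], bad)
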