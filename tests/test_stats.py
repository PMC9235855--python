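import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridcoord import (
    Arena,
    Trajectory,
    build_population,
    conditional_distributions,
    error_segments,
    generate_spikes,
    lagged_group_correlations,
    mae,
    null_delta,
    null_delta_closed_form,
    null_mae,
    pairwise_correlations,
    sem_correlated,
    simulate_trajectory,
    uniform_pair_distance_closed_form,
)
from gridcoord.synthetic import SpikeData, generate_spikes_from_rates


class TestSemCorrelated:
    def test_independent_samples_match_classical(self):
        x = np.random.default_rng(0).normal(0, 2, 50000)
        classical = x.std(ddof=0) / np.sqrt(len(x))
        assert sem_correlated(x) == pytest.approx(classical, rel=0.05)

    def test_ar1_matches_truncated_closed_form(self):
        rng = np.random.default_rng(1)
        rho, n = 0.5, 100000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(0, 1, n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        # lags with rho^i > 0.15: i = 1, 2 -> Var = ACF0 (1 + 2(0.5 + 0.25))
        closed = np.sqrt(x.var() * (1 + 2 * (rho + rho**2)) / n)
        assert sem_correlated(x) == pytest.approx(closed, rel=0.05)

    def test_constant_signal_zero(self):
        assert sem_correlated(np.full(100, 3.3)) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sem_correlated(np.array([1.0]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.0, 0.9))
    def test_at_least_classical_for_positive_correlation(self, seed, rho):
        rng = np.random.default_rng(seed)
        eps = rng.normal(0, 1, 2000)
        x = np.empty(2000)
        x[0] = eps[0]
        for t in range(1, 2000):
            x[t] = rho * x[t - 1] + eps[t]
        classical = x.std(ddof=0) / np.sqrt(len(x))
        assert sem_correlated(x) >= classical - 1e-12


class TestMae:
    def test_perfect_decoding_zero(self):
        p = np.random.default_rng(0).uniform(-50, 50, (100, 2))
        assert mae(p, p)[0] == 0.0

    def test_constant_offset(self):
        p = np.random.default_rng(1).uniform(-50, 50, (100, 2))
        assert mae(p + [6.0, 8.0], p)[0] == pytest.approx(10.0)

    def test_uniform_random_decoding_near_closed_form(self):
        rng = np.random.default_rng(2)
        n = 200000
        def disk(seed):
            g = np.random.default_rng(seed)
            r = 75 * np.sqrt(g.uniform(size=n))
            th = g.uniform(0, 2 * np.pi, n)
            return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        got, _ = mae(disk(3), disk(4))
        assert got == pytest.approx(uniform_pair_distance_closed_form(75.0),
                                    abs=0.5)


class TestNullMae:
    def test_pinned_center_trajectory(self):
        arena = Arena(radius=75.0)
        traj = Trajectory(times=np.arange(5000) / 120,
                          positions=np.zeros((5000, 2)), dt=1 / 120)
        got, sem = null_mae(traj, arena, realizations=30, seed=0)
        # mean distance from the center to a uniform point: (2/3) R = 50 cm
        assert got == pytest.approx(50.0, abs=0.3)
        assert sem < 0.5

    def test_tiny_arena_limit(self):
        arena = Arena(radius=0.5)
        traj = Trajectory(times=np.arange(100) / 120,
                          positions=np.zeros((100, 2)), dt=1 / 120)
        assert null_mae(traj, arena, realizations=5, seed=1)[0] < 0.5


class TestNullDelta:
    def test_monte_carlo_matches_closed_form(self):
        table = null_delta([45.0, 65.0, 95.0], realizations=10, seed=0)
        for _, row in table.iterrows():
            assert row["null_delta_cm"] == pytest.approx(
                row["closed_form_cm"], abs=0.05)

    def test_spacing_65_value(self):
        assert null_delta_closed_form(65.0) == pytest.approx(19.5)

    def test_vanishing_spacing(self):
        assert null_delta_closed_form(0.0) == 0.0


class TestPairwiseCorrelations:
    def test_duplicated_train_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        c = rng.poisson(0.2, size=1200).astype(np.int32)
        spikes = SpikeData(counts=np.stack([c, c]),
                           module_labels=np.array([0, 0]), dt=1 / 120)
        table = pairwise_correlations(spikes)
        assert table["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_trains_near_zero(self):
        # 30 min of independent constant-rate Poisson trains
        spikes = generate_spikes_from_rates(np.full((6, 216000), 8.0), 1 / 120,
                                            np.zeros(6), seed=1)
        table = pairwise_correlations(spikes)
        assert np.abs(table["r"]).max() < 0.02

    def test_correlations_explained_by_maps_and_trajectory(self):
        # regenerated Poisson spikes from the same curves and trajectory
        # reproduce the pair-correlation structure near the identity line
        arena = Arena()
        traj = simulate_trajectory(arena, 300.0, seed=2)
        specs = build_population([45.0, 95.0], [12, 12], seed=3)
        a = generate_spikes(specs, traj, seed=4, arena=arena)
        b = generate_spikes(specs, traj, seed=5, arena=arena)
        ra = pairwise_correlations(a)["r"]
        rb = pairwise_correlations(b)["r"]
        agree = np.corrcoef(ra, rb)[0, 1]
        assert agree > 0.9
        slope = np.polyfit(ra, rb, 1)[0]
        assert 0.8 < slope < 1.2

    def test_intra_exceeds_inter_at_zero_lag(self):
        arena = Arena()
        traj = simulate_trajectory(arena, 300.0, seed=6)
        specs = build_population([45.0, 95.0], [12, 12], seed=7)
        spikes = generate_spikes(specs, traj, seed=8, arena=arena)
        table = pairwise_correlations(spikes)
        intra = np.abs(table.loc[table["intra_module"], "r"]).mean()
        inter = np.abs(table.loc[~table["intra_module"], "r"]).mean()
        assert intra > inter


@pytest.fixture(scope="module")
def small_population():
    arena = Arena()
    traj = simulate_trajectory(arena, 300.0, seed=9)
    specs = build_population([45.0, 95.0], [20, 20], seed=10)
    return generate_spikes(specs, traj, seed=11, arena=arena)


class TestLaggedGroupCorrelations:
    def test_intra_exceeds_inter(self, small_population):
        table = lagged_group_correlations(small_population, max_lag=0.0, seed=0)
        intra = table.loc[table["kind"] == "intra", "mean_abs_r"].iloc[0]
        inter = table.loc[table["kind"] == "inter", "mean_abs_r"].iloc[0]
        assert intra > inter

    def test_zero_max_lag_single_row_per_kind(self, small_population):
        table = lagged_group_correlations(small_population, max_lag=0.0, seed=0)
        assert sorted(table["lag_s"].unique()) == [0.0]
        assert set(table["kind"]) == {"intra", "inter"}

    def test_group_count_reduced_for_few_neurons(self):
        spikes = generate_spikes_from_rates(
            np.full((6, 12000), 10.0), 1 / 120, np.array([0, 0, 0, 1, 1, 1]),
            seed=12)
        table = lagged_group_correlations(spikes, n_groups=10, max_lag=0.0,
                                          seed=1)
        assert table["n_groups"].max() <= 3


class TestErrorSegments:
    def test_constant_small_error_single_segment(self):
        seg = error_segments(np.full(7200, 5.0), 1 / 120)
        assert len(seg.small) == 1 and seg.small[0] == (0, 7200)
        assert seg.large == []

    def test_constant_large_error_below_cutoff(self):
        seg = error_segments(np.full(7200, 25.0), 1 / 120)
        assert len(seg.large) == 1 and seg.large[0] == (0, 7200)
        assert seg.small == []

    def test_square_wave_counts(self):
        # 2-s blocks of 5 / 25 cm over 60 s: 15 small and 15 large segments
        blocks = np.tile(np.r_[np.full(240, 5.0), np.full(240, 25.0)], 15)
        seg = error_segments(blocks, 1 / 120)
        assert len(seg.small) == 15
        assert len(seg.large) == 15

    def test_segments_disjoint_and_idempotent(self):
        rng = np.random.default_rng(3)
        err = np.abs(rng.normal(15, 10, 36000))
        seg = error_segments(err, 1 / 120)
        covered = np.zeros(len(err), dtype=int)
        for a, b in seg.small + seg.large:
            covered[a:b] += 1
            assert (b - a) >= 120  # >= 1 s
        assert covered.max() <= 1
        seg2 = error_segments(err, 1 / 120)
        assert seg.small == seg2.small and seg.large == seg2.large


class TestConditionalDistributions:
    def test_independent_samples_give_matching_distributions(self):
        rng = np.random.default_rng(4)
        delta = rng.gamma(4.0, 1.0, 50000)
        err = rng.uniform(0, 40, 50000)  # independent of delta
        table = conditional_distributions(delta, err, n_mae_bins=4)
        pivot = table.pivot_table(index="distance_mid", columns="mae_bin",
                                  values="density")
        spread = pivot.max(axis=1) - pivot.min(axis=1)
        assert spread.max() < 0.02

    def test_dependent_samples_differ(self):
        rng = np.random.default_rng(5)
        err = rng.uniform(0, 40, 50000)
        delta = rng.gamma(4.0, 1.0, 50000) + 0.3 * err
        table = conditional_distributions(delta, err, n_mae_bins=4)
        means = table.groupby("mae_bin").apply(
            lambda g: np.sum(g["distance_mid"] * g["density"]),
            include_groups=False)
        assert means.iloc[-1] > means.iloc[0] + 5.0
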