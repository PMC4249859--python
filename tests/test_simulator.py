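"""Tests of the Langevin propagation, neighbour indexing and proliferation."""

import numpy as np
import pytest
from scipy import stats

from ephsim.core_model import InteractionParams, equilibrium_separation, pair_force
from ephsim.fixtures import mixed_seeding
from ephsim.io_cli import RunConfig, DomainConfig, InitialConfig, NumericsConfig
from ephsim.simulator import (
    EPH,
    EPHRIN,
    BirthParams,
    Domain,
    MotilityParams,
    SimulationState,
    apply_births,
    build_neighbour_index,
    drift,
    max_stable_dt,
    reflect,
    run,
    step,
    total_potential_energy,
)

DT = 4.0 / 60.0  # default step, minutes


def make_state(positions, types=None, domain=None, seed=0, time=0.0):
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(positions)
    if types is None:
        types = np.zeros(n, dtype=np.int8)
    if domain is None:
        domain = Domain(10_000.0, 10_000.0)
    return SimulationState(
        time=time,
        ids=np.arange(n, dtype=np.int64),
        types=np.asarray(types, dtype=np.int8),
        positions=positions,
        last_division=np.zeros(n),
        domain=domain,
        rng=np.random.default_rng(seed),
    )


class TestNeighbourIndex:
    def test_collinear_cells(self):
        pos = np.array([[0.0, 0.0], [40.0, 0.0], [80.0, 0.0]])
        index = build_neighbour_index(pos, cutoff=45.0)
        assert list(index.query(1)) == [0, 2]
        assert list(index.query(0)) == [1]

    def test_matches_brute_force_on_random_cells(self, rng):
        pos = rng.uniform(0, 640, size=(500, 2))
        index = build_neighbour_index(pos, cutoff=45.0)
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        for i in range(500):
            expected = sorted(j for j in range(500) if j != i and d[i, j] <= 45.0)
            assert list(index.query(i)) == expected

    def test_pair_set_matches_brute_force(self, rng):
        pos = rng.uniform(0, 640, size=(300, 2))
        index = build_neighbour_index(pos, cutoff=60.0)
        got = {tuple(p) for p in index.pairs()}
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        expected = {
            (i, j) for i in range(300) for j in range(i + 1, 300) if d[i, j] <= 60.0
        }
        assert got == expected

    def test_empty_input(self):
        index = build_neighbour_index(np.empty((0, 2)), cutoff=45.0)
        assert len(index.pairs()) == 0


class TestDrift:
    def test_single_cell_has_zero_drift(self, interaction):
        state = make_state([[50.0, 50.0]])
        index = build_neighbour_index(state.positions, 60.0)
        np.testing.assert_array_equal(drift(state, interaction, index), 0.0)

    def test_total_drift_vanishes(self, interaction, rng):
        state = make_state(
            rng.uniform(0, 300, (80, 2)), types=rng.integers(0, 2, 80)
        )
        index = build_neighbour_index(state.positions, 60.0)
        total = drift(state, interaction, index).sum(axis=0)
        np.testing.assert_allclose(total, 0.0, atol=1e-9)

    def test_matches_pairwise_brute_force(self, interaction, rng):
        """Vectorized cutoff drift vs a scalar all-pairs pair_force loop."""
        n = 50
        pos = rng.uniform(0, 1000, (n, 2))
        types = rng.integers(0, 2, n)
        state = make_state(pos, types=types, domain=Domain(1000.0, 1000.0))
        index = build_neighbour_index(pos, cutoff=120.0)
        got = drift(state, interaction, index)
        names = {EPH: "EPH", EPHRIN: "EPHRIN"}
        expected = np.zeros((n, 2))
        for i in range(n):
            for j in range(n):
                if i != j:
                    expected[i] += pair_force(
                        pos[i], pos[j], names[types[i]], names[types[j]], interaction
                    )
        np.testing.assert_allclose(got, expected, atol=1e-4)


class TestStep:
    def test_no_noise_no_neighbours_is_identity(self, interaction):
        state = make_state([[100.0, 100.0], [500.0, 500.0]])
        out = step(state, DT, MotilityParams(D=0.0), interaction)
        np.testing.assert_array_equal(out.positions, state.positions)
        assert out.time == pytest.approx(DT)

    def test_unstable_dt_rejected(self, interaction):
        state = make_state([[0.0, 0.0]])
        dt_max = max_stable_dt(interaction)
        with pytest.raises(ValueError, match="maximum admissible dt"):
            step(state, 2 * dt_max, MotilityParams(D=0.0), interaction)

    def test_two_cells_relax_to_equilibrium_separation(self, interaction, default_params):
        d_star = equilibrium_separation(default_params)
        state = make_state([[480.0, 500.0], [520.0, 500.0]])  # d = 40 µm
        motility = MotilityParams(D=0.0)
        for _ in range(15_000):
            state = step(state, DT, motility, interaction)
        d = np.linalg.norm(state.positions[0] - state.positions[1])
        assert d == pytest.approx(d_star, abs=0.01)

    def test_free_diffusion_msd_slope(self):
        """Interaction-free MSD grows as 4·D·t (2-D diffusion law)."""
        D = 5.0
        n, n_steps, dt = 2000, 200, 1.0
        start = np.full((n, 2), 50_000.0)
        state = make_state(start, domain=Domain(100_000.0, 100_000.0), seed=42)
        msd = []
        for _ in range(n_steps):
            state = step(state, dt, MotilityParams(D=D), params=None)
            msd.append(((state.positions - start) ** 2).sum(axis=1).mean())
        t = dt * np.arange(1, n_steps + 1)
        slope = float(np.sum(t * msd) / np.sum(t * t))  # regression through origin
        assert slope == pytest.approx(4 * D, rel=0.05)

    def test_gradient_flow_energy_decreases(self, interaction, domain):
        state = mixed_seeding(25, 25, domain, seed=3, min_separation=4.0)
        energy = total_potential_energy(state, interaction)
        for _ in range(200):
            state = step(state, DT, MotilityParams(D=0.0), interaction)
            new_energy = total_potential_energy(state, interaction)
            assert new_energy <= energy + 1e-9
            energy = new_energy


class TestBirths:
    def test_zero_rate_is_identity(self):
        state = make_state([[1.0, 1.0], [2.0, 2.0]])
        out = apply_births(state, 10.0, BirthParams(beta=0.0))
        assert out is state

    def test_yule_mean_growth(self):
        """E[N(t)] = N0·e^(βt): two doublings over 48 h at β = ln2/24."""
        beta = BirthParams(beta=np.log(2) / 24.0)
        dt, n_steps = 10.0, 288  # 48 h in 10-min birth steps
        finals = []
        for seed in range(200):
            state = make_state(
                np.random.default_rng(seed).uniform(0, 5000, (100, 2)),
                domain=Domain(5000.0, 5000.0),
                seed=seed + 10_000,
            )
            for k in range(1, n_steps + 1):
                state.time = k * dt
                state = apply_births(state, dt, beta)
            finals.append(state.n_cells)
        assert np.mean(finals) == pytest.approx(400.0, rel=0.05)

    def test_division_counts_match_event_driven_oracle(self):
        """Per-step memoryless divisions vs an exact Gillespie oracle.

        The division count of any single cell over time T is a rate-β
        renewal count; the oracle simulates exponential inter-event times
        directly.  Two-sample chi-square on the histograms must not reject.
        """
        beta = np.log(2) / 24.0 / 60.0  # 1/min
        T, dt = 24 * 60.0, 6.0
        n_cells = 10_000
        state = make_state(
            np.random.default_rng(1).uniform(0, 50_000, (n_cells, 2)),
            domain=Domain(50_000.0, 50_000.0),
            seed=7,
        )
        counts = np.zeros(n_cells, dtype=int)
        bp = BirthParams(beta=np.log(2) / 24.0)
        n_steps = int(T / dt)
        for k in range(1, n_steps + 1):
            state.time = k * dt
            state = apply_births(state, dt, bp)
            counts += state.last_division[:n_cells] == k * dt

        oracle_rng = np.random.default_rng(99)
        gaps = oracle_rng.exponential(1.0 / beta, size=(n_cells, 12))
        oracle_counts = (np.cumsum(gaps, axis=1) <= T).sum(axis=1)

        edges = [-0.5, 0.5, 1.5, 2.5, np.inf]
        obs = np.histogram(counts, bins=edges)[0]
        exp = np.histogram(oracle_counts, bins=edges)[0]
        _, p, _, _ = stats.chi2_contingency(np.vstack([obs, exp]))
        assert p > 0.01

    def test_daughters_inherit_type_and_get_fresh_ids(self):
        state = make_state(
            [[10.0, 10.0], [20.0, 20.0]], types=[EPH, EPHRIN], time=5.0
        )
        out = apply_births(state, 1e6, BirthParams(beta=10.0))  # certain division
        assert out.n_cells == 4
        assert len(np.unique(out.ids)) == 4
        np.testing.assert_array_equal(np.sort(out.types), [0, 0, 1, 1])
        # daughters 1 µm from their mothers
        for k in (2, 3):
            d = np.linalg.norm(out.positions[k] - out.positions[k - 2])
            assert d == pytest.approx(1.0)
        assert np.all(out.last_division == 5.0)


class TestReflect:
    def test_mirror_at_wall(self):
        np.testing.assert_allclose(
            reflect(np.array([-3.0, 10.0]), Domain(100.0, 100.0)), [3.0, 10.0]
        )

    def test_periodic_wrap(self):
        np.testing.assert_allclose(
            reflect(np.array([103.0, 10.0]), Domain(100.0, 100.0, "PERIODIC")),
            [3.0, 10.0],
        )

    def test_interior_unchanged(self):
        np.testing.assert_allclose(
            reflect(np.array([[50.0, 60.0]]), Domain(100.0, 100.0)), [[50.0, 60.0]]
        )

    def test_positions_stay_inside_during_run(self):
        config = RunConfig(
            seed=5,
            domain=DomainConfig(width=160.0, height=160.0),
            initial=InitialConfig(n_eph=8, n_ephrin=8),
            numerics=NumericsConfig(duration_h=0.5, output_interval_min=5.0),
        )
        for snap in run(config):
            assert np.all(snap.positions >= 0)
            assert np.all(snap.positions <= 160.0)


class TestRun:
    def test_zero_duration_gives_initial_snapshot_only(self):
        config = RunConfig(
            initial=InitialConfig(n_eph=4, n_ephrin=4),
            domain=DomainConfig(width=200.0, height=200.0),
            numerics=NumericsConfig(duration_h=0.0),
        )
        traj = run(config)
        assert len(traj) == 1
        assert traj.snapshots[0].time == 0.0
        assert traj.snapshots[0].n_cells == 8

    def test_population_never_shrinks_and_times_increase(self):
        config = RunConfig(
            seed=11,
            initial=InitialConfig(n_eph=16, n_ephrin=16),
            domain=DomainConfig(width=320.0, height=320.0),
            numerics=NumericsConfig(duration_h=2.0, output_interval_min=20.0),
        )
        traj = run(config)
        times = traj.times
        assert times[0] == 0.0
        assert np.all(np.diff(times) > 0)
        counts = [s.n_cells for s in traj]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_same_seed_reproduces_trajectory(self):
        config = RunConfig(
            seed=21,
            initial=InitialConfig(n_eph=10, n_ephrin=10),
            domain=DomainConfig(width=320.0, height=320.0),
            numerics=NumericsConfig(duration_h=1.0, output_interval_min=20.0),
        )
        t1, t2 = run(config), run(config)
        assert len(t1) == len(t2)
        for s1, s2 in zip(t1, t2):
            np.testing.assert_array_equal(s1.positions, s2.positions)
            np.testing.assert_array_equal(s1.ids, s2.ids)
            np.testing.assert_array_equal(s1.types, s2.types)
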