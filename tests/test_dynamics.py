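"""Cluster initialization, the stochastic stepper, and trajectory contracts."""

import numpy as np
import pytest

from collective_guidance.chemo_signal import SignalField
from collective_guidance.coattraction import CoattractionParams
from collective_guidance.dynamics import (
    CLOSED_SHELL_SIZES,
    InstabilityError,
    ModelParams,
    SimulationState,
    init_hexagonal_cluster,
    polarity_rate,
    run_ensemble,
    run_trajectory,
    step,
)

UNIFORM = SignalField(kind="uniform", S0=1.0)


class TestInitCluster:
    def test_single_cell_at_origin(self):
        np.testing.assert_allclose(init_hexagonal_cluster(1), 0.0)

    def test_seven_cell_closed_shell(self):
        pos = init_hexagonal_cluster(7, rotate=False)
        d = np.linalg.norm(pos, axis=1)
        assert np.isclose(d.min(), 0.0)
        np.testing.assert_allclose(np.sort(d)[1:], 1.0, atol=1e-12)

    def test_nineteen_cell_shells(self):
        pos = init_hexagonal_cluster(19, rotate=False)
        d = np.sort(np.linalg.norm(pos, axis=1))
        assert d.max() == pytest.approx(2.0)
        # shells: 1 center, 6 at distance 1, 6 at sqrt(3), 6 at 2
        np.testing.assert_allclose(d[1:7], 1.0, atol=1e-12)
        np.testing.assert_allclose(d[7:13], np.sqrt(3.0), atol=1e-12)

    @pytest.mark.parametrize("n", CLOSED_SHELL_SIZES[:5])
    def test_closed_shells_have_unit_nearest_neighbors(self, n):
        pos = init_hexagonal_cluster(n, rotate=False)
        if n == 1:
            return
        diff = pos[:, None] - pos[None, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        np.testing.assert_allclose(dist.min(axis=1), 1.0, atol=1e-12)

    def test_centroid_at_origin_and_rotation_reproducible(self):
        a = init_hexagonal_cluster(12, rng=3)
        b = init_hexagonal_cluster(12, rng=3)
        np.testing.assert_allclose(a.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_array_equal(a, b)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            init_hexagonal_cluster(0)


class TestPolarityRate:
    def test_isolated_cell_pure_decay(self):
        st = SimulationState(
            t=0.0,
            positions=np.zeros((1, 2)),
            polarities=np.array([[2.0, -1.0]]),
            rng=np.random.default_rng(0),
        )
        params = ModelParams(beta_bar=20.0, tau=2.0)
        np.testing.assert_allclose(
            polarity_rate(st, params, UNIFORM), [[-1.0, 0.5]], atol=1e-14
        )

    def test_pair_gains_outward_cil_bias(self):
        pos = np.array([[0.55, 0.0], [-0.55, 0.0]])
        st = SimulationState(
            t=0.0, positions=pos, polarities=np.zeros((2, 2)),
            rng=np.random.default_rng(0),
        )
        params = ModelParams(beta_bar=20.0)
        rate = polarity_rate(st, params, UNIFORM)
        np.testing.assert_allclose(rate[0], [20.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(rate[1], [-20.0, 0.0], atol=1e-12)

    def test_interior_cell_of_hexagon_only_decays(self, hex7):
        p = np.zeros((7, 2))
        p[0] = [0.3, 0.4]  # ordering: first site is the lattice center
        st = SimulationState(
            t=0.0, positions=hex7, polarities=p, rng=np.random.default_rng(0)
        )
        params = ModelParams(beta_bar=20.0)
        rate = polarity_rate(st, params, UNIFORM)
        center = int(np.argmin(np.linalg.norm(hex7, axis=1)))
        np.testing.assert_allclose(rate[center], -p[center] / params.tau, atol=1e-12)


class TestStep:
    def test_deterministic_decay_exact_euler(self):
        params = ModelParams(sigma=0.0, dt=1e-3)
        st = SimulationState(
            t=0.0, positions=np.zeros((1, 2)),
            polarities=np.array([[1.0, 0.0]]), rng=np.random.default_rng(0),
        )
        new = step(st, params, UNIFORM)
        np.testing.assert_allclose(new.polarities, [[1.0 - 1e-3, 0.0]], rtol=1e-14)
        np.testing.assert_allclose(new.positions, [[1e-3, 0.0]], rtol=1e-14)

    def test_step_halving_first_order_convergence(self):
        """Deterministic two-cell collision converges O(dt) under refinement."""
        pol0 = np.array([[-0.8, 0.1], [0.8, -0.1]])
        pos0 = np.array([[0.55, 0.0], [-0.55, 0.0]])

        def final_pos(dt, n):
            params = ModelParams.loose(sigma=0.0, beta_bar=30.0, dt=dt)
            st = SimulationState(
                t=0.0, positions=pos0.copy(), polarities=pol0.copy(),
                rng=np.random.default_rng(0),
            )
            for _ in range(n):
                st = step(st, params, UNIFORM)
            return st.positions

        # fixed horizon T = 0.2
        ref = final_pos(0.2 / 3200, 3200)
        e1 = np.abs(final_pos(0.2 / 400, 400) - ref).max()
        e2 = np.abs(final_pos(0.2 / 800, 800) - ref).max()
        assert e1 > e2
        assert e1 / e2 == pytest.approx(2.0, rel=0.3)

    def test_centroid_velocity_is_mean_polarity(self, hex7):
        """Internal forces cancel: the centroid moves with the mean polarity."""
        rng = np.random.default_rng(4)
        params = ModelParams(dt=1e-4, beta_bar=20.0)
        st = SimulationState(
            t=0.0, positions=hex7 * 1.01, polarities=rng.normal(size=(7, 2)),
            rng=rng,
        )
        new = step(st, params, UNIFORM)
        drift = (new.positions.mean(axis=0) - st.positions.mean(axis=0)) / params.dt
        np.testing.assert_allclose(drift, st.polarities.mean(axis=0), atol=1e-10)

    def test_large_dt_with_stiff_springs_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            ModelParams(dt=5e-2, v_r=500.0, v_a=500.0)

    def test_instability_raises_with_advice(self):
        # dt far beyond the explicit stability limit of the polarity decay
        params = ModelParams(dt=11.0, tau=1.0, sigma=0.0, v_r=0.0, v_a=0.0, beta_bar=0.0)
        st = SimulationState(
            t=0.0, positions=np.zeros((1, 2)),
            polarities=np.array([[1.0, 0.0]]), rng=np.random.default_rng(0),
        )
        with pytest.raises(InstabilityError, match="dt"), np.errstate(over="ignore", invalid="ignore"):
            for _ in range(500):
                st = step(st, params, UNIFORM)


class TestRunTrajectory:
    def test_same_seed_same_record(self):
        params = ModelParams.loose(beta_bar=10.0, coattraction=CoattractionParams(chi=5.0))
        a = run_trajectory(params, UNIFORM, 5, 1.0, seed=11, snapshot_dt=0.1)
        b = run_trajectory(params, UNIFORM, 5, 1.0, seed=11, snapshot_dt=0.1)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.polarities, b.polarities)

    def test_single_cell_fast_path_matches_generic_stepper(self):
        """The vectorized isolated-cell integrator consumes the RNG stream
        identically to the generic per-step loop."""
        params = ModelParams(beta_bar=0.0, v_r=0.0, v_a=0.0, dt=1e-3)
        fast = run_trajectory(params, UNIFORM, 1, 2.0, seed=7, snapshot_dt=0.1)
        generic = run_trajectory(
            params, UNIFORM, 1, 2.0, seed=7, snapshot_dt=0.1,
            initial_polarities=np.zeros((1, 2)),
        )
        np.testing.assert_allclose(fast.polarities, generic.polarities, atol=1e-12)
        np.testing.assert_allclose(fast.positions, generic.positions, atol=1e-12)

    def test_polarity_variance_matches_ou_theory(self):
        """Stationary polarity variance per component is sigma^2 tau."""
        params = ModelParams(sigma=0.7, tau=1.0, dt=1e-3, v_r=0.0, v_a=0.0, beta_bar=0.0)
        traj = run_trajectory(params, UNIFORM, 1, 3000.0, seed=5, snapshot_dt=0.5)
        p = traj.polarities[20:, 0, :]  # drop the burn-in from p(0) = 0
        var = p.var(axis=0)
        expected = params.sigma**2 * params.tau
        # ~ T / (2 tau) effectively independent samples per component
        n_eff = 3000.0 / 2.0
        tol = 3.0 * expected * np.sqrt(2.0 / n_eff)
        assert np.all(np.abs(var - expected) < tol)

    def test_velocity_autocorrelation_time(self):
        """The isolated-cell velocity decorrelates on the timescale tau."""
        params = ModelParams(tau=1.0, dt=1e-3, v_r=0.0, v_a=0.0, beta_bar=0.0)
        traj = run_trajectory(params, UNIFORM, 1, 2000.0, seed=9, snapshot_dt=0.1)
        p = traj.polarities[100:, 0, 0]
        p = p - p.mean()
        lags = np.arange(1, 21)  # 0.1 tau .. 2 tau
        ac = np.array([np.dot(p[:-k], p[k:]) / np.dot(p, p) for k in lags])
        slope = np.polyfit(lags * 0.1, np.log(ac), 1)[0]
        assert -slope == pytest.approx(1.0 / params.tau, rel=0.1)

    def test_long_time_diffusion_constant(self):
        """MSD of an isolated cell is diffusive with D = sigma^2 tau^2."""
        params = ModelParams(dt=1e-3, v_r=0.0, v_a=0.0, beta_bar=0.0)
        n = 200
        t_end = 100.0
        disp = np.empty((n, 2))
        for k in range(n):
            traj = run_trajectory(params, UNIFORM, 1, t_end, seed=[77, k], snapshot_dt=t_end)
            disp[k] = traj.positions[-1, 0] - traj.positions[0, 0]
        msd = (disp**2).sum(axis=1).mean()
        # OU-driven MSD at t >> tau: 4 sigma^2 tau^2 (t - tau)
        expected = 4.0 * (t_end - 1.0)
        se = (disp**2).sum(axis=1).std(ddof=1) / np.sqrt(n)
        assert abs(msd - expected) < 3.0 * se

    def test_snapshot_cadence_and_determinism_of_ensembles(self):
        params = ModelParams.loose(beta_bar=5.0)
        trajs = run_ensemble(params, UNIFORM, 3, 0.5, n_traj=2, master_seed=2, snapshot_dt=0.1)
        assert len(trajs) == 2
        np.testing.assert_allclose(np.diff(trajs[0].times), 0.1, atol=1e-12)
        # trajectory k depends only on (master_seed, k)
        again = run_trajectory(params, UNIFORM, 3, 0.5, seed=[2, 1], snapshot_dt=0.1)
        np.testing.assert_array_equal(trajs[1].positions, again.positions)

    def test_legi_quasi_static_runs_and_records_R(self, hex7):
        from collective_guidance.chemo_signal import LegiRates

        params = ModelParams(
            beta_bar=20.0, dt=1e-4, legi=LegiRates(), response_mode="legi_linear"
        )
        field = SignalField(kind="exponential", S0=1.0, S1=0.025)
        traj = run_trajectory(params, field, 7, 0.05, seed=0, snapshot_dt=0.01)
        assert traj.R is not None and traj.R.shape == (6, 7)
        assert np.all(traj.R > 0)

    def test_dataframe_round_trip(self):
        params = ModelParams.loose(beta_bar=5.0)
        traj = run_trajectory(params, UNIFORM, 3, 0.2, seed=1, snapshot_dt=0.1)
        df = traj.to_dataframe()
        assert set(df.columns) == {"t", "cell_id", "x", "y", "px", "py"}
        assert len(df) == len(traj.times) * 3


def test_step_consistent_with_polarity_rate():
    """The stepper's fused update equals the documented polarity rate
    (guards the two code paths against drifting apart)."""
    from collective_guidance.chemo_signal import LegiRates
    from collective_guidance.dynamics import _init_legi_state

    rng = np.random.default_rng(0)
    pos = rng.normal(size=(9, 2)) * 1.5
    field = SignalField(kind="exponential", S0=1.0, S1=0.025)

    def make(sigma):
        return ModelParams.loose(
            beta_bar=20.0, legi=LegiRates(), response_mode="legi_linear",
            coattraction=CoattractionParams(chi=10.0, ell=5.0), sigma=sigma,
        )

    legi0 = _init_legi_state(pos, make(1.0), field, 0.0)
    pol = rng.normal(size=(9, 2))
    st = SimulationState(
        t=0.0, positions=pos, polarities=pol, rng=np.random.default_rng(5), legi=legi0
    )
    rate = polarity_rate(st, make(1.0), field)
    params0 = make(0.0)
    new = step(
        SimulationState(
            t=0.0, positions=pos.copy(), polarities=pol.copy(),
            rng=np.random.default_rng(5), legi=legi0,
        ),
        params0, field,
    )
    implied = (new.polarities - pol) / params0.dt
    np.testing.assert_allclose(implied, rate, atol=1e-10)
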