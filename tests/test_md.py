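import numpy as np
import pytest

from disolv.md import (MDConfig, ZeroForceField, init_velocities,
                       instantaneous_temperature, langevin_step, run_md)
from disolv.prior import PriorForceField
from disolv.synthetic import FixtureSpec, make_ionic_box
from disolv.system import make_system
from disolv.units import KB


class _Harmonic:
    """Independent central-spring force field for integrator oracles."""

    cutoff = 0.3

    def __init__(self, k, center):
        self.k = k
        self.center = center

    def compute(self, positions, pairs):
        d = positions - self.center
        return 0.5 * self.k * float(np.sum(d * d)), -self.k * d


class TestInitVelocities:
    def test_kinetic_temperature_near_target(self):
        n = 10_000
        system = make_system(np.zeros((n, 3)), ["Na"] * n, (100, 100, 100))
        v = init_velocities(system, 300.0, seed=0)
        t = instantaneous_temperature(system, v)
        assert t == pytest.approx(300.0, rel=0.02)

    def test_frozen_particles_at_rest_and_momentum_removed(self):
        system = make_system(np.zeros((50, 3)), ["Na"] * 50, (10, 10, 10),
                             mobile=[k % 2 == 0 for k in range(50)])
        v = init_velocities(system, 300.0, seed=1)
        np.testing.assert_array_equal(v[~system.mobile], 0.0)
        p = (system.masses[:, None] * v)[system.mobile].sum(axis=0)
        np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_nonpositive_temperature_rejected(self):
        system = make_system(np.zeros((2, 3)), ["Na"] * 2, (5, 5, 5))
        with pytest.raises(ValueError):
            init_velocities(system, 0.0)


class TestInstantaneousTemperature:
    def test_all_velocities_zero(self):
        system = make_system(np.zeros((5, 3)), ["Na"] * 5, (5, 5, 5))
        assert instantaneous_temperature(system, np.zeros((5, 3))) == 0.0

    def test_single_mobile_particle_uses_three_dof(self):
        system = make_system(np.zeros((1, 3)), ["Na"], (5, 5, 5))
        v = np.array([[0.5, 0.0, 0.0]])
        ke = 0.5 * system.masses[0] * 0.25
        expected = 2 * ke / (KB * 3)
        assert instantaneous_temperature(system, v) == pytest.approx(expected)

    def test_no_mobile_particles_is_error(self):
        system = make_system(np.zeros((2, 3)), ["Na"] * 2, (5, 5, 5),
                             mobile=[False, False])
        with pytest.raises(ValueError):
            instantaneous_temperature(system, np.zeros((2, 3)))


class TestLangevinStep:
    def test_gamma_to_zero_matches_velocity_verlet_recursion(self):
        """Thermostat off: positions must follow the closed-form velocity
        Verlet recursion x_{n+1} = 2 x_n - x_{n-1} + dt^2 F(x_n)/m."""
        k, m = 250.0, 22.99
        center = np.array([5.0, 5.0, 5.0])
        ff = _Harmonic(k, center)
        system = make_system([[5.4, 5.0, 5.0]], ["Na"], (10, 10, 10))
        v0 = np.array([[0.0, 0.2, 0.0]])
        cfg = MDConfig(dt=0.002, thermostat=False, n_steps=200,
                       save_every=0.002, seed=0)
        traj = run_md(system, ff, cfg, velocities=v0)
        x = traj.positions[:, 0, :] - center
        dt = cfg.dt
        # independent recursion from the same first two states
        xs = [x[0], x[1]]
        for _ in range(2, len(x)):
            xs.append(2 * xs[-1] - xs[-2] + dt * dt * (-k * xs[-1]) / m)
        np.testing.assert_allclose(x, np.array(xs), atol=1e-11)

    def test_ou_stationary_velocity_variance(self):
        n = 2000
        rng = np.random.default_rng(0)
        system = make_system(rng.random((n, 3)) * 50, ["Na"] * n, (50, 50, 50))
        cfg = MDConfig(n_steps=3000, save_every=0.05, seed=2)
        traj = run_md(system, ZeroForceField(), cfg)
        t_mean = np.mean(traj.log["temperature"][20:])
        assert t_mean == pytest.approx(300.0, rel=0.02)

    def test_frozen_particles_never_move(self):
        spec = FixtureSpec(concentration=0.5, box=(3.0, 3.0, 3.0), seed=2)
        system = make_ionic_box(spec)
        system.mobile[:4] = False
        frozen_coords = system.positions[:4].copy()
        traj = run_md(system, PriorForceField(system),
                      MDConfig(n_steps=500, save_every=0.05, seed=3))
        for frame in traj.positions:
            np.testing.assert_array_equal(frame[:4], frozen_coords)

    def test_langevin_step_function_advances_state(self):
        system = make_system([[2.0, 2.0, 2.0]], ["Na"], (5, 5, 5))
        v = np.array([[0.1, 0.0, 0.0]])
        new_system, new_v, forces = langevin_step(
            system, v, ZeroForceField(), MDConfig(seed=0))
        assert new_system.positions[0, 0] != system.positions[0, 0]
        assert forces.shape == (1, 3)


class TestRunMD:
    def test_zero_steps_yields_initial_frame_only(self):
        system = make_ionic_box(FixtureSpec(box=(3, 3, 3), seed=4))
        traj = run_md(system, PriorForceField(system),
                      MDConfig(n_steps=0, seed=0))
        assert len(traj) == 1
        np.testing.assert_array_equal(traj.positions[0], system.positions)

    def test_nve_energy_conservation_short(self):
        system = make_ionic_box(FixtureSpec(box=(3.2, 3.2, 3.2), seed=5))
        ff = PriorForceField(system)
        warm = run_md(system, ff, MDConfig(n_steps=1500, save_every=1.5, seed=5))
        s_eq = warm.frame(-1)
        v = init_velocities(s_eq, 300.0, seed=6)
        traj = run_md(s_eq, ff, MDConfig(n_steps=2000, save_every=0.05,
                                         thermostat=False, seed=0),
                      velocities=v)
        e = traj.log["e_pot"] + traj.log["e_kin"]
        assert np.max(np.abs(e - e[0])) / abs(e[0]) < 1e-4

    def test_nve_momentum_conservation(self):
        system = make_ionic_box(FixtureSpec(box=(3.2, 3.2, 3.2), seed=5))
        ff = PriorForceField(system)
        v = init_velocities(system, 300.0, seed=6)
        cfg = MDConfig(n_steps=2000, save_every=0.5, thermostat=False, seed=0,
                       save_velocities=True)
        traj = run_md(system, ff, cfg, velocities=v)
        p_final = (system.masses[:, None] * traj.velocities[-1]).sum(axis=0)
        assert np.linalg.norm(p_final) < 1e-8

    def test_reproducible_for_fixed_seed(self):
        system = make_ionic_box(FixtureSpec(box=(3, 3, 3), seed=7))
        ff = PriorForceField(system)
        a = run_md(system, ff, MDConfig(n_steps=300, save_every=0.1, seed=11))
        b = run_md(system, ff, MDConfig(n_steps=300, save_every=0.1, seed=11))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_trajectory_times_strictly_increasing(self):
        system = make_ionic_box(FixtureSpec(box=(3, 3, 3), seed=7))
        traj = run_md(system, PriorForceField(system),
                      MDConfig(n_steps=300, save_every=0.05, seed=1))
        assert np.all(np.diff(traj.times) > 0)

    def test_kick_variant_also_thermostats(self):
        n = 500
        rng = np.random.default_rng(3)
        system = make_system(rng.random((n, 3)) * 30, ["Na"] * n, (30, 30, 30))
        cfg = MDConfig(n_steps=2000, save_every=0.05, seed=2, variant="kick")
        traj = run_md(system, ZeroForceField(), cfg)
        assert np.mean(traj.log["temperature"][20:]) == pytest.approx(300.0, rel=0.03)


def test_unwrapped_positions_track_images():
    # one fast particle crossing the boundary several times
    system = make_system([[0.5, 0.5, 0.5]], ["Na"], (1.0, 1.0, 1.0))
    v = np.array([[1.0, 0.0, 0.0]])
    cfg = MDConfig(n_steps=2500, save_every=0.1, thermostat=False, seed=0)
    traj = run_md(system, ZeroForceField(), cfg, velocities=v)
    unwrapped = traj.unwrapped_positions()[:, 0, 0]
    expected = 0.5 + traj.times * 1.0
    np.testing.assert_allclose(unwrapped, expected, atol=1e-9)
    assert np.all(traj.positions[:, 0, 0] < 1.0)
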