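"""Verlet integration, coupling, and trajectory diagnostics."""

import math

import numpy as np
import pytest

from mncat.dynamics import (
    BarostatSettings,
    ColdStartError,
    IntegratorState,
    MDSettings,
    PRESETS,
    ThermostatSettings,
    Trajectory,
    barostat_update,
    bootstrap_previous_position,
    instantaneous_temperature,
    kabsch_superpose,
    maxwell_boltzmann_velocities,
    minimize_steepest_descent,
    run_md,
    thermostat_update,
    trajectory_rmsd,
    trajectory_rmsf,
    verlet_step,
)
from mncat.energetics import BondParam, ForceFieldParameters, PairParam
from mncat.system import AtomSite, ToySystem
from mncat.units import ACC, KB


def oscillator(kb=100.0, r0=1.5, stretch=0.1):
    system = ToySystem(
        atoms=[AtomSite("C", [0, 0, 0]), AtomSite("C", [r0 + stretch, 0, 0])],
        bonds=[(0, 1)],
    )
    params = ForceFieldParameters(bonds={(0, 1): BondParam(kb, r0)},
                                  include_electrostatics=False)
    return system, params


def analytic_period(kb, mass):
    """Bond energy K(r-r0)^2 on a dimer: reduced mass mu, spring constant 2K."""
    mu = mass / 2.0
    return 2.0 * math.pi * math.sqrt(mu / (2.0 * kb * ACC))


class TestIntegrator:
    def test_bootstrap_at_rest(self):
        pos = np.zeros((2, 3))
        state = bootstrap_previous_position(pos, np.zeros((2, 3)), np.zeros((2, 3)),
                                            np.array([12.0, 12.0]), dt=1.0)
        assert np.allclose(state.prev_positions, pos)

    def test_bootstrap_constant_force(self):
        pos = np.zeros((1, 3))
        f = np.array([[10.0, 0.0, 0.0]])
        m = np.array([2.0])
        state = bootstrap_previous_position(pos, f, np.zeros((1, 3)), m, dt=1.0)
        assert state.prev_positions[0, 0] == pytest.approx(0.5 * ACC * 10.0 / 2.0)

    def test_bootstrap_harmonic_first_step(self):
        # r(t-dt) from the Taylor start matches the analytic cosine to O(dt^3)
        kb, m, x0, dt = 100.0, 12.0, 0.1, 0.01
        omega = math.sqrt(2 * kb * ACC / m)
        pos = np.array([[x0, 0.0, 0.0]])
        f = np.array([[-2 * kb * x0, 0.0, 0.0]])
        state = bootstrap_previous_position(pos, f, np.zeros((1, 3)),
                                            np.array([m]), dt=dt)
        analytic = x0 * math.cos(omega * dt)
        assert state.prev_positions[0, 0] == pytest.approx(analytic, abs=1e-9)

    def test_zero_force_straight_line(self):
        state = IntegratorState(
            positions=np.array([[1.0, 0, 0]]),
            prev_positions=np.array([[0.9, 0, 0]]),
            masses=np.array([1.0]), dt=1.0,
        )
        for _ in range(5):
            verlet_step(state, np.zeros((1, 3)))
        assert state.positions[0, 0] == pytest.approx(1.5)

    def test_oscillator_period_and_drift(self):
        kb = 100.0
        system, params = oscillator(kb)
        period = analytic_period(kb, 12.011)
        dt = period / 1000.0
        traj = run_md(system, params, MDSettings(dt=dt), 10000)
        energies = np.array(traj.energies)
        drift = (energies.max() - energies.min()) / abs(energies.mean())
        assert drift <= 1e-4
        # period from upward zero crossings of the bond extension
        x = np.array([f[1, 0] - f[0, 0] - 1.5 for f in traj.frames])
        t = np.array(traj.times)
        idx = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
        crossings = t[idx] - x[idx] * (t[idx + 1] - t[idx]) / (x[idx + 1] - x[idx])
        measured = np.diff(crossings).mean()
        assert measured == pytest.approx(period, rel=1e-3)


class TestThermostat:
    def test_at_target_no_rescale(self):
        rng = np.random.default_rng(0)
        masses = np.full(8, 12.0)
        v = maxwell_boltzmann_velocities(masses, 300.0, rng)
        state = IntegratorState(
            positions=np.zeros((8, 3)), prev_positions=-v * 1.0,
            masses=masses, dt=1.0,
        )
        t_now = instantaneous_temperature(state.velocities(), masses)
        settings = ThermostatSettings(target_temperature=t_now, tau=100.0)
        before = state.prev_positions.copy()
        thermostat_update(state, settings)
        assert np.allclose(state.prev_positions, before, atol=1e-12)

    def test_infinite_tau_decouples(self):
        rng = np.random.default_rng(1)
        masses = np.full(4, 12.0)
        v = maxwell_boltzmann_velocities(masses, 500.0, rng)
        state = IntegratorState(np.zeros((4, 3)), -v, masses, dt=1.0)
        before = state.prev_positions.copy()
        thermostat_update(state, ThermostatSettings(300.0, tau=1e12))
        assert np.allclose(state.prev_positions, before, atol=1e-9)

    def test_cold_start_raises(self):
        state = IntegratorState(np.zeros((4, 3)), np.zeros((4, 3)),
                                np.full(4, 12.0), dt=1.0)
        with pytest.raises(ColdStartError):
            thermostat_update(state, ThermostatSettings(300.0, 100.0))

    def test_free_gas_exponential_relaxation(self):
        """A force-free gas relaxes toward the target as exp(-t/tau)."""
        rng = np.random.default_rng(5)
        masses = np.full(20, 39.9)
        t_start, t_target, tau, dt = 600.0, 300.0, 200.0, 2.0
        v = maxwell_boltzmann_velocities(masses, t_start, rng)
        state = IntegratorState(np.zeros((20, 3)), -v * dt, masses, dt=dt)
        t0 = instantaneous_temperature(state.velocities(), masses)
        settings = ThermostatSettings(t_target, tau)
        temps = []
        for _ in range(500):
            verlet_step(state, np.zeros((20, 3)))
            thermostat_update(state, settings)
            temps.append(instantaneous_temperature(state.velocities(), masses))
        times = dt * np.arange(1, 501)
        expected = t_target + (t0 - t_target) * np.exp(-times / tau)
        # no forces: the relaxation is deterministic up to the discrete-step factor
        assert np.abs(np.array(temps) - expected).max() / t_target < 0.01


class TestBarostat:
    def make_state(self, box=10.0):
        return IntegratorState(np.ones((2, 3)), np.ones((2, 3)),
                               np.full(2, 12.0), dt=1.0, box_length=box)

    def test_fixed_point(self):
        state = self.make_state()
        settings = BarostatSettings(external_pressure=0.5, cell_mass=100.0)
        barostat_update(state, settings, internal_pressure=0.5)
        assert state.box_length == pytest.approx(10.0)

    def test_growth_arithmetic(self):
        state = self.make_state()
        settings = BarostatSettings(external_pressure=0.0, cell_mass=100.0)
        barostat_update(state, settings, internal_pressure=2.0)
        assert state.box_length == pytest.approx(10.0 * (1 + 1.0 / 100.0 * 2.0))
        assert np.allclose(state.positions, (1 + 0.02) * np.ones((2, 3)))

    def test_two_updates_compose_to_first_order(self):
        s1 = self.make_state()
        settings = BarostatSettings(external_pressure=0.0, cell_mass=1000.0)
        barostat_update(s1, settings, 1.0)
        barostat_update(s1, settings, 2.0)
        s2 = self.make_state()
        barostat_update(s2, settings, 3.0)
        assert s1.box_length == pytest.approx(s2.box_length, rel=1e-5)

    def test_requires_box(self):
        state = IntegratorState(np.ones((2, 3)), np.ones((2, 3)),
                                np.full(2, 12.0), dt=1.0)
        with pytest.raises(ValueError, match="box"):
            barostat_update(state, BarostatSettings(), 1.0)


class TestRunMd:
    def test_zero_steps_single_frame(self):
        system, params = oscillator()
        traj = run_md(system, params, MDSettings(dt=0.5), 0)
        assert traj.n_frames == 1

    def test_determinism_bit_identical(self):
        system, params = oscillator()
        settings = MDSettings(dt=0.5, initial_temperature=300.0,
                              thermostat=ThermostatSettings(300.0, 100.0))
        t1 = run_md(system.copy(), params, settings, 200, seed=42)
        t2 = run_md(system.copy(), params, settings, 200, seed=42)
        assert all(np.array_equal(a, b) for a, b in zip(t1.frames, t2.frames))
        assert t1.energies == t2.energies

    def test_seed_required_for_velocities(self):
        system, params = oscillator()
        with pytest.raises(ValueError, match="seed"):
            run_md(system, params, MDSettings(initial_temperature=300.0), 10)

    def test_lj_dimer_stays_bound_near_minimum(self):
        # well depth 0.9 kcal/mol >> kT at 20 K, so the dimer must stay bound
        pp = PairParam(1.0e5, 600.0)
        system = ToySystem(atoms=[
            AtomSite("Ar", [0, 0, 0], mass=39.9),
            AtomSite("Ar", [pp.r_min, 0, 0], mass=39.9),
        ])
        params = ForceFieldParameters(pairs={("Ar", "Ar"): pp},
                                      include_electrostatics=False)
        traj = run_md(system, params,
                      MDSettings(dt=2.0, initial_temperature=20.0), 5000, seed=3)
        sep = np.array([np.linalg.norm(f[1] - f[0]) for f in traj.frames])
        assert sep.max() < 2.0 * pp.r_min           # stays bound at low T
        assert sep.mean() == pytest.approx(pp.r_min, rel=0.05)

    def test_thermostatted_mean_temperature(self):
        """20-atom LJ gas under the thermostat holds the target within 2%."""
        rng = np.random.default_rng(8)
        pp = PairParam(1.0e5, 200.0)
        # jittered lattice: no close contacts that would destabilize the start
        grid = np.array([[i, j, k] for i in range(3) for j in range(3)
                         for k in range(3)], dtype=float)
        coords = 4.0 * grid[:20] + rng.uniform(-0.3, 0.3, size=(20, 3))
        system = ToySystem(
            atoms=[AtomSite("Ar", xyz, mass=39.9) for xyz in coords],
            box_length=12.0,
        )
        params = ForceFieldParameters(pairs={("Ar", "Ar"): pp},
                                      include_electrostatics=False)
        settings = MDSettings(dt=5.0, stride=10, initial_temperature=300.0,
                              thermostat=ThermostatSettings(300.0, 500.0))
        traj = run_md(system, params, settings, 20000, seed=12)
        mean_t = np.mean(traj.temperatures[len(traj.temperatures) // 4:])
        assert mean_t == pytest.approx(300.0, rel=0.02)

    def test_production_preset_is_declared(self):
        stages = [s["stage"] for s in PRESETS["production"]]
        assert stages == ["minimize", "nvt", "npt", "production"]
        assert PRESETS["production"][0]["steps"] == 5000


class TestMinimize:
    def test_stretched_bond_relaxes(self):
        system, params = oscillator(stretch=0.4)
        relaxed, energy = minimize_steepest_descent(system, params)
        assert energy == pytest.approx(0.0, abs=1e-8)
        sep = np.linalg.norm(relaxed.positions[1] - relaxed.positions[0])
        assert sep == pytest.approx(1.5, abs=1e-4)


def make_traj(frames):
    traj = Trajectory()
    for k, f in enumerate(frames):
        traj.append(float(k), f, None, 0.0, 0.0)
    return traj


class TestRmsd:
    def test_reference_vs_itself(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(6, 3))
        assert trajectory_rmsd(make_traj([f, f]))[1] == pytest.approx(0.0, abs=1e-12)

    def test_rotated_copy_superposes_to_zero(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=(6, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        g = f @ q.T + np.array([3.0, -2.0, 1.0])
        assert trajectory_rmsd(make_traj([f, g]))[1] == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_closed_form(self):
        rng = np.random.default_rng(2)
        n, d = 8, 0.7
        f = rng.normal(size=(n, 3))
        g = f.copy()
        g[0, 0] += d
        # without superposition the closed form d/sqrt(N) holds exactly
        val = trajectory_rmsd(make_traj([f, g]), align=False)[1]
        assert val == pytest.approx(d / math.sqrt(n))
        # optimal superposition can only lower it
        assert trajectory_rmsd(make_traj([f, g]))[1] <= val + 1e-12


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=(5, 3))
        assert np.allclose(trajectory_rmsf(make_traj([f, f, f])), 0.0)

    def test_single_frame_raises(self):
        with pytest.raises(ValueError, match="two frames"):
            trajectory_rmsf(make_traj([np.zeros((3, 3))]))

    def test_two_state_and_sinusoid_closed_forms(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(6, 3)) * 4
        a = 0.3
        # balanced two-state +-a on one atom: RMSF exactly a (no alignment)
        frames = []
        for s in (+1, -1, +1, -1):
            g = base.copy()
            g[2, 1] += s * a
            frames.append(g)
        rmsf = trajectory_rmsf(make_traj(frames), align=False)
        assert rmsf[2] == pytest.approx(a)
        assert np.abs(np.delete(rmsf, 2)).max() == 0.0
        # full-period sinusoidal sampling: RMSF -> a/sqrt(2)
        phases = 2 * np.pi * np.arange(64) / 64
        frames = []
        for ph in phases:
            g = base.copy()
            g[2, 1] += a * math.sin(ph)
            frames.append(g)
        rmsf = trajectory_rmsf(make_traj(frames), align=False)
        assert rmsf[2] == pytest.approx(a / math.sqrt(2), rel=1e-6)

    def test_isotropic_jitter_gives_sigma_sqrt3(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(10, 3)) * 5
        sigma = 0.12
        frames = [base + sigma * rng.normal(size=(10, 3)) for _ in range(4000)]
        rmsf = trajectory_rmsf(make_traj(frames), align=False)
        assert np.mean(rmsf) == pytest.approx(sigma * math.sqrt(3), rel=0.02)


def test_kabsch_recovers_rotation():
    rng = np.random.default_rng(7)
    p = rng.normal(size=(9, 3))
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = p @ q.T + 5.0
    assert np.allclose(kabsch_superpose(moved, p), p, atol=1e-9)
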