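"""Position-Verlet dynamics with weak temperature/pressure coupling.

The integrator is the position (Størmer) Verlet recursion

    r(t+Δt) = 2 r(t) - r(t-Δt) + (F(t)/m) Δt²

in the package unit system (Å, fs, amu, kcal/mol), which conserves energy on
toy force fields to the expected O(Δt²) fluctuation.  There are no explicit
velocities: effective velocities are central differences of the position
history, and the Berendsen-style thermostat

    T(t+Δt) = T(t) + (Δt/τ_T) (T_target - T(t))

acts by rescaling the implied velocities (i.e. adjusting r(t-Δt)).  The
barostat applies the isotropic weak-coupling box update
``h(t+Δt) = h(t) + (Δt/W)(P_int - P_ext) h(t)`` with affine coordinate
scaling; the full cell-matrix form is an extension point the toy systems do
not need.

Convergence diagnostics (RMSD against a reference frame after optimal
superposition, per-atom RMSF about the mean structure) live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .energetics import ForceFieldParameters, mm_forces, mm_total_energy
from .system import ToySystem
from .units import ACC, KB

__all__ = [
    "IntegratorState",
    "ThermostatSettings",
    "BarostatSettings",
    "MDSettings",
    "Trajectory",
    "ColdStartError",
    "AbortedRunError",
    "maxwell_boltzmann_velocities",
    "instantaneous_temperature",
    "bootstrap_previous_position",
    "verlet_step",
    "thermostat_update",
    "barostat_update",
    "run_md",
    "minimize_steepest_descent",
    "kabsch_superpose",
    "trajectory_rmsd",
    "trajectory_rmsf",
    "virial_pressure",
    "PRESETS",
]


class ColdStartError(RuntimeError):
    """Thermostat invoked at T = 0; initialize velocities first."""


class AbortedRunError(RuntimeError):
    """Energy diverged; carries the trajectory up to the last stable frame."""

    def __init__(self, message: str, trajectory: "Trajectory"):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class IntegratorState:
    """Positions now and one step back, plus timestep, masses and box."""

    positions: np.ndarray        # r(t), Å
    prev_positions: np.ndarray   # r(t-Δt), Å
    masses: np.ndarray           # amu
    dt: float                    # fs
    step: int = 0
    box_length: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.prev_positions = np.asarray(self.prev_positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.positions.shape != self.prev_positions.shape:
            raise ValueError("position arrays must be congruent")
        if self.dt <= 0:
            raise ValueError("timestep must be positive")

    def velocities(self) -> np.ndarray:
        """Backward-difference effective velocities (r(t) - r(t-Δt))/Δt, Å/fs."""
        return (self.positions - self.prev_positions) / self.dt


@dataclass
class ThermostatSettings:
    target_temperature: float = 300.0   # K
    tau: float = 100.0                  # fs
    enabled: bool = True

    def __post_init__(self):
        if self.target_temperature <= 0:
            raise ValueError("target temperature must be positive")


@dataclass
class BarostatSettings:
    external_pressure: float = 0.0   # kcal/(mol·Å³)
    cell_mass: float = 1.0e5         # coupling parameter W, fs·(pressure unit)/Å-ish
    enabled: bool = True

    def __post_init__(self):
        if self.cell_mass <= 0:
            raise ValueError("cell mass parameter must be positive")


@dataclass
class Trajectory:
    """Time-ordered frames with thermodynamic state."""

    times: list[float] = field(default_factory=list)           # fs
    frames: list[np.ndarray] = field(default_factory=list)     # (N, 3) Å
    box_lengths: list[float | None] = field(default_factory=list)
    temperatures: list[float] = field(default_factory=list)    # K
    energies: list[float] = field(default_factory=list)        # kcal/mol (total)

    def append(self, time, positions, box_length, temperature, energy) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("frame times must be strictly increasing")
        self.times.append(float(time))
        self.frames.append(np.array(positions, dtype=float))
        self.box_lengths.append(box_length)
        self.temperatures.append(float(temperature))
        self.energies.append(float(energy))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def positions_array(self) -> np.ndarray:
        """(n_frames, N, 3) stacked coordinates."""
        return np.stack(self.frames)


# ---------------------------------------------------------------------------
# Velocities and temperature
# ---------------------------------------------------------------------------

def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator,
    remove_com: bool = True,
) -> np.ndarray:
    """Draw velocities (Å/fs) at the given temperature; COM motion removed."""
    masses = np.asarray(masses, dtype=float)
    sigma = np.sqrt(KB * temperature * ACC / masses)
    v = rng.normal(size=(masses.size, 3)) * sigma[:, None]
    if remove_com and masses.size > 1:
        v -= np.average(v, axis=0, weights=masses)
    return v


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kcal/mol from velocities in Å/fs."""
    return float(0.5 * np.sum(masses[:, None] * velocities**2) / ACC)


def instantaneous_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic temperature with 3N-3 degrees of freedom (COM removed)."""
    n = masses.size
    dof = 3 * n - 3 if n > 1 else 3
    return 2.0 * kinetic_energy(velocities, masses) / (dof * KB)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def bootstrap_previous_position(
    positions: np.ndarray, forces: np.ndarray, velocities: np.ndarray,
    masses: np.ndarray, dt: float, box_length: float | None = None,
) -> IntegratorState:
    """Second-order Taylor start: r(t-Δt) = r(t) - vΔt + (F/2m)Δt² (a in Å/fs²)."""
    positions = np.asarray(positions, dtype=float)
    acc = ACC * np.asarray(forces, dtype=float) / np.asarray(masses, dtype=float)[:, None]
    prev = positions - velocities * dt + 0.5 * acc * dt**2
    return IntegratorState(
        positions=positions.copy(), prev_positions=prev, masses=np.asarray(masses, float),
        dt=dt, box_length=box_length,
    )


def verlet_step(state: IntegratorState, forces: np.ndarray) -> IntegratorState:
    """Advance one position-Verlet step in place; returns the state."""
    forces = np.asarray(forces, dtype=float)
    if not np.all(np.isfinite(forces)):
        raise AbortedRunError(
            f"non-finite force at step {state.step}", Trajectory()
        )
    acc = ACC * forces / state.masses[:, None]
    new = 2.0 * state.positions - state.prev_positions + acc * state.dt**2
    state.prev_positions = state.positions
    state.positions = new
    state.step += 1
    return state


def thermostat_update(state: IntegratorState, settings: ThermostatSettings) -> IntegratorState:
    """Berendsen velocity rescaling toward the target temperature.

    The rescale factor is sqrt(T_new/T) with T_new = T + (Δt/τ)(T_target - T);
    rescaling acts on the position history (r(t-Δt) is pulled toward r(t)).
    """
    if not settings.enabled:
        return state
    v = state.velocities()
    t_now = instantaneous_temperature(v, state.masses)
    if t_now <= 0.0:
        raise ColdStartError(
            "instantaneous temperature is zero; draw initial velocities "
            "(maxwell_boltzmann_velocities) before thermostatting"
        )
    t_new = t_now + (state.dt / settings.tau) * (settings.target_temperature - t_now)
    lam = math.sqrt(max(t_new, 0.0) / t_now)
    state.prev_positions = state.positions - lam * (state.positions - state.prev_positions)
    return state


def barostat_update(
    state: IntegratorState, settings: BarostatSettings, internal_pressure: float
) -> IntegratorState:
    """Isotropic weak-coupling box update with affine coordinate scaling."""
    if not settings.enabled:
        return state
    if state.box_length is None:
        raise ValueError("barostat requires a periodic box")
    scale = 1.0 + (state.dt / settings.cell_mass) * (
        internal_pressure - settings.external_pressure
    )
    state.box_length *= scale
    state.positions = state.positions * scale
    state.prev_positions = state.prev_positions * scale
    return state


def virial_pressure(
    positions: np.ndarray, forces: np.ndarray, velocities: np.ndarray,
    masses: np.ndarray, volume: float,
) -> float:
    """Scalar virial pressure, kcal/(mol·Å³): (2·KE + Σ r·F) / (3V)."""
    ke = kinetic_energy(velocities, masses)
    vir = float(np.sum(positions * forces))
    return (2.0 * ke + vir) / (3.0 * volume)


# ---------------------------------------------------------------------------
# The MD driver
# ---------------------------------------------------------------------------

@dataclass
class MDSettings:
    dt: float = 2.0                        # fs, production default
    stride: int = 1                        # frame recording interval
    initial_temperature: float | None = None
    thermostat: ThermostatSettings | None = None
    barostat: BarostatSettings | None = None
    energy_bound: float = 1.0e8            # kcal/mol, divergence abort
    remove_com: bool = True


#: The production protocol, encoded as a named preset (stage, steps, settings hints).
#: Tests and examples exercise the same machinery at far smaller step counts.
PRESETS = {
    "production": (
        {"stage": "minimize", "steps": 5000, "method": "steepest_descent"},
        {"stage": "nvt", "time_ns": 10, "dt_fs": 2.0, "temperature": 300.0},
        {"stage": "npt", "time_ns": 20, "dt_fs": 2.0, "temperature": 300.0,
         "pressure_atm": 1.0},
        {"stage": "production", "time_ns": 100, "dt_fs": 2.0},
    ),
}


def run_md(
    system: ToySystem,
    params: ForceFieldParameters,
    settings: MDSettings,
    n_steps: int,
    seed: int | None = None,
    force_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    energy_fn: Callable[[np.ndarray], float] | None = None,
) -> Trajectory:
    """Integrate ``n_steps`` of dynamics and record a trajectory.

    Forces default to the toy force field; a custom ``force_fn(positions)``
    (and matching ``energy_fn``) may replace it.  A fixed ``seed`` makes the
    run bit-identical; a seed is mandatory whenever initial velocities are
    drawn from the Maxwell-Boltzmann distribution.
    """
    masses = system.masses
    pos = system.positions

    if force_fn is None:
        work = system.copy()

        def force_fn(p: np.ndarray) -> np.ndarray:
            work.positions = p
            return mm_forces(work, params)

        def energy_fn(p: np.ndarray) -> float:
            work.positions = p
            return mm_total_energy(work, params).total

    if settings.initial_temperature is not None:
        if seed is None:
            raise ValueError("drawing initial velocities requires a seed")
        rng = np.random.default_rng(seed)
        vel = maxwell_boltzmann_velocities(
            masses, settings.initial_temperature, rng, settings.remove_com
        )
    else:
        vel = np.zeros_like(pos)

    forces = force_fn(pos)
    state = bootstrap_previous_position(
        pos, forces, vel, masses, settings.dt, system.box_length
    )

    traj = Trajectory()

    def record(time_fs, positions, velocities) -> float:
        pe = energy_fn(positions) if energy_fn is not None else 0.0
        total = pe + kinetic_energy(velocities, masses)
        traj.append(
            time_fs, positions, state.box_length,
            instantaneous_temperature(velocities, masses), total,
        )
        if not math.isfinite(total) or abs(total) > settings.energy_bound:
            raise AbortedRunError(
                f"energy diverged at t = {time_fs} fs (E = {total:.3g} kcal/mol)", traj
            )
        return total

    record(0.0, state.positions, vel)
    if n_steps == 0:
        return traj

    dt = settings.dt
    for step in range(1, n_steps + 1):
        old_prev = state.prev_positions          # r(step-2) (or bootstrap ghost)
        old_pos = state.positions                # r(step-1)
        verlet_step(state, forces)               # -> r(step)
        # frame step-1 gets central-difference velocities, O(Δt²) accurate
        if step >= 2 and (step - 1) % settings.stride == 0:
            v_central = (state.positions - old_prev) / (2.0 * dt)
            record((step - 1) * dt, old_pos, v_central)
        if settings.thermostat is not None:
            thermostat_update(state, settings.thermostat)
        forces = force_fn(state.positions)
        if settings.barostat is not None:
            volume = (state.box_length or 0.0) ** 3
            if volume <= 0:
                raise ValueError("barostat requires a periodic box")
            p_int = virial_pressure(
                state.positions, forces, state.velocities(), masses, volume
            )
            barostat_update(state, settings.barostat, p_int)
            forces = force_fn(state.positions)
    # final frame: one virtual Verlet step supplies the central velocity
    acc = ACC * forces / masses[:, None]
    ghost = 2.0 * state.positions - state.prev_positions + acc * dt**2
    v_central = (ghost - state.prev_positions) / (2.0 * dt)
    record(n_steps * dt, state.positions, v_central)
    return traj


def minimize_steepest_descent(
    system: ToySystem,
    params: ForceFieldParameters,
    max_steps: int = 5000,
    step_size: float = 1.0e-3,
    force_tol: float = 1.0e-6,
) -> tuple[ToySystem, float]:
    """Steepest-descent minimisation with step halving on energy increase."""
    work = system.copy()
    energy = mm_total_energy(work, params).total
    alpha = step_size
    for _ in range(max_steps):
        forces = mm_forces(work, params)
        if float(np.abs(forces).max(initial=0.0)) < force_tol:
            break
        trial = work.positions + alpha * forces
        saved = work.positions
        work.positions = trial
        e_new = mm_total_energy(work, params).total
        if e_new < energy:
            energy = e_new
            alpha *= 1.1
        else:
            work.positions = saved
            alpha *= 0.5
            if alpha < 1e-12:
                break
    return work, energy


# ---------------------------------------------------------------------------
# Superposition diagnostics
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rigid superposition of ``mobile`` onto ``reference`` (both (N, 3))."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + reference.mean(axis=0)


def _select(coords: np.ndarray, selection: Sequence[int] | None) -> np.ndarray:
    if selection is None:
        return coords
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("atom selection is empty")
    if selection.max(initial=-1) >= coords.shape[0] or selection.min(initial=0) < 0:
        raise ValueError("atom selection out of range")
    return coords[selection]


def trajectory_rmsd(
    traj: Trajectory,
    reference_frame: int = 0,
    atom_selection: Sequence[int] | None = None,
    align: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) against a reference frame, optionally superposed."""
    ref = _select(traj.frames[reference_frame], atom_selection)
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        coords = _select(frame, atom_selection)
        if coords.shape != ref.shape:
            raise ValueError("selection mismatch between frames")
        if align:
            coords = kabsch_superpose(coords, ref)
        out[k] = math.sqrt(float(np.mean(np.sum((coords - ref) ** 2, axis=1))))
    return out


def trajectory_rmsf(
    traj: Trajectory,
    atom_selection: Sequence[int] | None = None,
    align: bool = True,
) -> np.ndarray:
    """Per-atom RMSF (Å) about the mean structure after per-frame superposition."""
    if traj.n_frames < 2:
        raise ValueError("RMSF is undefined for fewer than two frames")
    frames = [_select(f, atom_selection) for f in traj.frames]
    if align:
        ref = frames[0]
        frames = [kabsch_superpose(f, ref) for f in frames]
        mean = np.mean(frames, axis=0)
        frames = [kabsch_superpose(f, mean) for f in frames]
    mean = np.mean(frames, axis=0)
    sq = np.mean([np.sum((f - mean) ** 2, axis=1) for f in frames], axis=0)
    return np.sqrt(sq)
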