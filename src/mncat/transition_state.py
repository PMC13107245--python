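"""Transition-state search and validation.

The elastic-band chain-of-states force on interior image ``i`` is

    F_i = -∇E(R_i) + κ (R_{i+1} - 2 R_i + R_{i-1})

i.e. the plain (non-projected) elastic band; the climbing-image variant
replaces the force on the highest-energy interior image by the true force
with its component along the local chord tangent inverted (and no spring
force), driving that image uphill to the saddle.  Defaults follow the
reference protocol: 10 images, spring constant 5.0 eV/Å² and force
tolerances 0.05 / 0.02 eV/Å (stored converted to kcal/mol units).

A located saddle is validated the way transition states are in practice:
a central-difference Hessian, mass-weighted normal modes, the requirement
of exactly one imaginary frequency whose mode lies along the declared
reaction coordinate, and steepest-descent paths launched off the saddle
along ± the imaginary mode that must terminate in the reactant and product
basins.  Imaginary wavenumbers are reported as omega = C·sqrt(|λ|/m_eff)
with C the package conversion constant for kcal/(mol·Å²)/amu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .surfaces import PotentialSurface
from .units import EV_TO_KCAL, FREQ_CM

__all__ = [
    "NebSettings",
    "NebResult",
    "HessianResult",
    "neb_forces",
    "run_neb",
    "finite_difference_hessian",
    "normal_modes",
    "classify_stationary_point",
    "descend_path",
    "activation_energy",
]


@dataclass
class NebSettings:
    n_images: int = 10
    spring: float = 5.0 * EV_TO_KCAL            # kcal/(mol·Å²), from 5.0 eV/Å²
    max_force_tol: float = 0.05 * EV_TO_KCAL    # kcal/(mol·Å), from 0.05 eV/Å
    rms_force_tol: float = 0.02 * EV_TO_KCAL    # kcal/(mol·Å), from 0.02 eV/Å
    climbing: bool = True
    max_iterations: int = 20000
    step_size: float = 2.0e-3                   # Å²·mol/kcal, steepest-descent scale

    def __post_init__(self):
        if self.n_images < 3:
            raise ValueError("an elastic band needs at least 3 images")
        if min(self.max_force_tol, self.rms_force_tol, self.spring) <= 0:
            raise ValueError("spring constant and force tolerances must be positive")


@dataclass
class NebResult:
    images: np.ndarray            # (n_images, d) optimized configurations
    energies: np.ndarray          # per-image energies, kcal/mol
    saddle_index: int
    barrier_forward: float        # kcal/mol, saddle minus first endpoint
    barrier_reverse: float        # kcal/mol, saddle minus last endpoint
    converged: bool
    iterations: int


@dataclass
class HessianResult:
    eigenvalues: np.ndarray           # mass-weighted, kcal/(mol·Å²·amu)
    eigenvectors: np.ndarray          # columns, orthonormal in mass-weighted space
    frequencies: np.ndarray           # cm⁻¹; negative entries denote imaginary modes
    n_imaginary: int
    reduced_masses: np.ndarray        # amu per mode

    @property
    def imaginary_frequencies(self) -> np.ndarray:
        """Magnitudes (cm⁻¹) of the imaginary modes."""
        return -self.frequencies[self.frequencies < 0]


# ---------------------------------------------------------------------------
# Chain-of-states forces and optimization
# ---------------------------------------------------------------------------

def neb_forces(
    images: np.ndarray, surface: PotentialSurface, settings: NebSettings,
    climbing_index: int | None = None,
) -> np.ndarray:
    """Per-image elastic-band forces; endpoints are fixed (zero force).

    ``climbing_index`` selects the image that receives the climbing-image
    force (true force with the tangent component inverted, no springs).
    """
    images = np.asarray(images, dtype=float)
    if images.shape[0] < 3:
        raise ValueError("an elastic band needs at least 3 images")
    n = images.shape[0]
    forces = np.zeros_like(images)
    for i in range(1, n - 1):
        grad = surface.grad(images[i])
        if i == climbing_index:
            tau = images[i + 1] - images[i - 1]
            tau = tau / np.linalg.norm(tau)
            forces[i] = -grad + 2.0 * float(np.dot(grad, tau)) * tau
        else:
            spring = settings.spring * (images[i + 1] - 2.0 * images[i] + images[i - 1])
            forces[i] = -grad + spring
    return forces


def _force_norms(forces: np.ndarray) -> tuple[float, float]:
    interior = forces[1:-1]
    if interior.size == 0:
        return 0.0, 0.0
    fmax = float(np.abs(interior).max())
    frms = float(np.sqrt(np.mean(interior**2)))
    return fmax, frms


def run_neb(
    start: np.ndarray, end: np.ndarray, surface: PotentialSurface,
    settings: NebSettings | None = None,
) -> NebResult:
    """Optimize a linearly interpolated band between two minima.

    Plain elastic-band optimization by damped steepest descent; the climbing
    image activates once the plain band is within 10× the force tolerance,
    always selecting the currently highest interior image (lowest index on
    ties).  Non-convergence is reported on the result, not raised.
    """
    settings = settings or NebSettings()
    start = np.atleast_1d(np.asarray(start, dtype=float))
    end = np.atleast_1d(np.asarray(end, dtype=float))
    n = settings.n_images
    images = np.linspace(start, end, n)

    if np.allclose(start, end):
        energies = np.array([surface.energy(im) for im in images])
        return NebResult(
            images=images, energies=energies, saddle_index=int(np.argmax(energies)),
            barrier_forward=float(energies.max() - energies[0]),
            barrier_reverse=float(energies.max() - energies[-1]),
            converged=True, iterations=0,
        )

    alpha = settings.step_size
    climbing_index: int | None = None
    best_fmax = math.inf
    worse_streak = 0
    converged = False
    iteration = 0

    for iteration in range(1, settings.max_iterations + 1):
        if settings.climbing and climbing_index is None:
            fmax, _ = _force_norms(neb_forces(images, surface, settings))
            if fmax < 10.0 * settings.max_force_tol:
                energies = np.array([surface.energy(im) for im in images])
                climbing_index = 1 + int(np.argmax(energies[1:-1]))
                # the climbing force differs from the band force: restart the
                # step-size control for the new objective
                best_fmax = math.inf
                worse_streak = 0
                alpha = settings.step_size
        forces = neb_forces(images, surface, settings, climbing_index)
        fmax, frms = _force_norms(forces)
        if fmax < settings.max_force_tol and frms < settings.rms_force_tol:
            if not settings.climbing or climbing_index is not None:
                converged = True
                break
        # adaptive damping: halve the step if the force keeps growing, let it
        # recover toward the nominal size while the force is dropping
        if fmax < best_fmax:
            best_fmax = fmax
            worse_streak = 0
            alpha = min(alpha * 1.05, settings.step_size)
        else:
            worse_streak += 1
            if worse_streak >= 10:
                alpha = max(alpha * 0.5, 1e-8)
                worse_streak = 0
        step = alpha * forces
        limit = np.abs(step).max(initial=0.0)
        if limit > 0.1:  # Å cap per iteration
            step *= 0.1 / limit
        images = images + step

    energies = np.array([surface.energy(im) for im in images])
    saddle = 1 + int(np.argmax(energies[1:-1]))
    return NebResult(
        images=images,
        energies=energies,
        saddle_index=saddle,
        barrier_forward=float(energies[saddle] - energies[0]),
        barrier_reverse=float(energies[saddle] - energies[-1]),
        converged=converged,
        iterations=iteration,
    )


# ---------------------------------------------------------------------------
# Hessian, normal modes, classification
# ---------------------------------------------------------------------------

def finite_difference_hessian(
    surface: PotentialSurface, point: np.ndarray, step: float = 1.0e-4
) -> np.ndarray:
    """Symmetric central-difference Hessian at ``point`` (symmetrized (H+Hᵀ)/2)."""
    if step <= 0:
        raise ValueError("finite-difference step must be positive")
    x = np.atleast_1d(np.asarray(point, dtype=float))
    d = x.size
    h = np.empty((d, d))
    for i in range(d):
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        gp = surface.grad(xp)
        gm = surface.grad(xm)
        h[i] = (gp - gm) / (2.0 * step)
    return 0.5 * (h + h.T)


def normal_modes(hessian: np.ndarray, masses: np.ndarray | None = None) -> HessianResult:
    """Mass-weighted normal modes of a (symmetric) Hessian.

    ``masses`` are per coordinate (amu); unit masses by default.  Negative
    mass-weighted eigenvalues are reported as imaginary frequencies with
    negative sign in ``frequencies``.
    """
    hessian = np.asarray(hessian, dtype=float)
    if not np.allclose(hessian, hessian.T, atol=1e-8 * max(1.0, np.abs(hessian).max())):
        raise ValueError("Hessian must be symmetric")
    d = hessian.shape[0]
    masses = np.ones(d) if masses is None else np.asarray(masses, dtype=float)
    inv_sqrt_m = 1.0 / np.sqrt(masses)
    hmw = hessian * np.outer(inv_sqrt_m, inv_sqrt_m)
    eigvals, eigvecs = np.linalg.eigh(hmw)
    freqs = np.sign(eigvals) * FREQ_CM * np.sqrt(np.abs(eigvals))
    # reduced mass per mode from the Cartesian displacement pattern
    reduced = np.empty(d)
    for k in range(d):
        cart = inv_sqrt_m * eigvecs[:, k]
        cart = cart / np.linalg.norm(cart)
        reduced[k] = 1.0 / float(np.sum(cart**2 / masses))
    return HessianResult(
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        frequencies=freqs,
        n_imaginary=int(np.sum(eigvals < 0)),
        reduced_masses=reduced,
    )


def classify_stationary_point(
    result: HessianResult,
    reaction_coordinate: np.ndarray | list[int] | None = None,
    overlap_threshold: float = 0.5,
) -> str:
    """Classify a stationary point: minimum / transition_state / higher_order_saddle.

    A first-order saddle is a valid transition state only if the imaginary
    mode's displacement lies predominantly on the declared reaction
    coordinate: overlap = norm of the mode restricted to those coordinates
    must reach ``overlap_threshold``.  ``reaction_coordinate`` may be a list
    of coordinate indices or an explicit direction vector; ``None`` accepts
    any single-imaginary-mode saddle.
    """
    if result.n_imaginary == 0:
        return "minimum"
    if result.n_imaginary > 1:
        return "higher_order_saddle"
    mode = result.eigenvectors[:, int(np.argmin(result.eigenvalues))]
    if reaction_coordinate is None:
        return "transition_state"
    rc = np.asarray(reaction_coordinate)
    if rc.dtype.kind in "iu":
        overlap = float(np.linalg.norm(mode[rc]))
    else:
        direction = rc / np.linalg.norm(rc)
        overlap = abs(float(np.dot(mode, direction)))
    return "transition_state" if overlap >= overlap_threshold else "higher_order_saddle"


# ---------------------------------------------------------------------------
# Descent validation and activation energy
# ---------------------------------------------------------------------------

def descend_path(
    surface: PotentialSurface,
    saddle_point: np.ndarray,
    mode_direction: np.ndarray,
    step: float = 1.0e-2,
    max_steps: int = 50000,
    grad_tol: float = 1.0e-6,
    displacement: float = 1.0e-2,
) -> tuple[np.ndarray, np.ndarray]:
    """Steepest-descent relaxations from saddle ± ε·mode; returns the two endpoints.

    The intrinsic-reaction-coordinate analogue at toy scale: each path must
    terminate at a point of vanishing gradient, and the two endpoints are
    compared with the reactant/product minima.
    """
    saddle_point = np.atleast_1d(np.asarray(saddle_point, dtype=float))
    mode = np.atleast_1d(np.asarray(mode_direction, dtype=float))
    mode = mode / np.linalg.norm(mode)

    def relax(x0: np.ndarray) -> np.ndarray:
        x = x0.copy()
        alpha = step
        energy = surface.energy(x)
        for _ in range(max_steps):
            g = surface.grad(x)
            if float(np.linalg.norm(g)) < grad_tol:
                break
            trial = x - alpha * g
            e_new = surface.energy(trial)
            if e_new <= energy + 1e-15:
                x, energy = trial, e_new
                alpha = min(alpha * 1.1, 10.0 * step)
            else:
                alpha *= 0.5
                if alpha < 1e-14:
                    raise RuntimeError("descent stalled: step size underflow")
        return x

    return (
        relax(saddle_point + displacement * mode),
        relax(saddle_point - displacement * mode),
    )


def activation_energy(neb: NebResult, reactant_energy: float | None = None) -> float:
    """Barrier: saddle energy minus the reactant energy (first endpoint by default).

    An unconverged band still yields a value, with a warning attached.
    """
    if not neb.converged:
        import warnings

        warnings.warn("activation energy computed from an unconverged band")
    e_reactant = neb.energies[0] if reactant_energy is None else reactant_energy
    return float(neb.energies[neb.saddle_index] - e_reactant)
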