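"""Elastic-band saddle search, Hessian/normal-mode validation, descent paths."""

import math

import numpy as np
import pytest
import sympy

from mncat.surfaces import PotentialSurface
from mncat.synthetic import SurfaceSpec, gen_double_well_surface
from mncat.transition_state import (
    NebSettings,
    activation_energy,
    classify_stationary_point,
    descend_path,
    finite_difference_hessian,
    neb_forces,
    normal_modes,
    run_neb,
)
from mncat.units import FREQ_CM


def flat_surface(dim=2):
    return PotentialSurface(lambda x: 0.0, lambda x: np.zeros_like(x), dimension=dim)


class TestNebForces:
    def test_flat_equally_spaced_is_fixed_point(self):
        images = np.linspace([0.0, 0.0], [1.0, 1.0], 5)
        f = neb_forces(images, flat_surface(), NebSettings(n_images=5))
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-12)

    def test_displaced_image_feels_pure_spring_force(self):
        settings = NebSettings(n_images=3, spring=10.0)
        images = np.array([[0.0, 0.0], [0.5, 0.3], [1.0, 0.0]])
        f = neb_forces(images, flat_surface(), settings)
        expected = 10.0 * (images[0] + images[2] - 2 * images[1])
        assert np.allclose(f[1], expected)
        assert np.allclose(f[0], 0.0) and np.allclose(f[2], 0.0)

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError):
            neb_forces(np.zeros((2, 1)), flat_surface(1), NebSettings())
        with pytest.raises(ValueError):
            NebSettings(n_images=2)


class TestRunNeb:
    def test_start_equals_end(self):
        surface, _ = gen_double_well_surface(SurfaceSpec())
        res = run_neb(np.array([-1.0]), np.array([-1.0]), surface)
        assert res.converged
        assert res.barrier_forward == pytest.approx(0.0, abs=1e-12)

    def test_quartic_double_well_barrier(self):
        """CI-NEB with 10 images recovers the a=5 analytic barrier within 1%."""
        surface, truth = gen_double_well_surface(SurfaceSpec(barrier=5.0))
        res = run_neb(truth.minima[0], truth.minima[1], surface)
        assert res.converged
        assert res.barrier_forward == pytest.approx(5.0, rel=0.01)
        # the climbing image sits at the analytic maximum
        assert res.images[res.saddle_index][0] == pytest.approx(0.0, abs=0.05)

    def test_climbing_image_refines_plain_band(self):
        surface, truth = gen_double_well_surface(SurfaceSpec(barrier=5.0))
        plain = run_neb(truth.minima[0], truth.minima[1], surface,
                        NebSettings(climbing=False))
        ci = run_neb(truth.minima[0], truth.minima[1], surface)
        assert abs(ci.barrier_forward - 5.0) <= abs(plain.barrier_forward - 5.0) + 1e-9

    def test_2d_surface_matches_grid_truth(self):
        surface, truth = gen_double_well_surface(
            SurfaceSpec(kind="two_minimum_2d", grid_resolution=801)
        )
        # tighter force tolerances: the barrier region is nearly flat, so the
        # default (loose) stopping criteria would leave the climbing image
        # short of the saddle by more than the 0.5% comparison window
        settings = NebSettings(max_force_tol=0.02, rms_force_tol=0.01)
        res = run_neb(truth.minima[0], truth.minima[1], surface, settings)
        assert res.converged
        assert res.energies[res.saddle_index] == pytest.approx(
            truth.saddle_energy, abs=0.005 * abs(truth.saddle_energy) + 1e-6
        )

    def test_tilted_well_barrier_asymmetry(self):
        surface, truth = gen_double_well_surface(SurfaceSpec(barrier=5.0, tilt=1.0))
        res = run_neb(truth.minima[0], truth.minima[1], surface)
        assert res.barrier_forward == pytest.approx(truth.barrier_forward, rel=0.01)
        assert res.barrier_reverse == pytest.approx(truth.barrier_reverse, rel=0.01)
        assert res.barrier_forward != pytest.approx(res.barrier_reverse, rel=0.01)

    def test_band_energies_unimodal_when_converged(self):
        surface, truth = gen_double_well_surface(SurfaceSpec(barrier=5.0))
        res = run_neb(truth.minima[0], truth.minima[1], surface)
        e = res.energies
        k = res.saddle_index
        assert np.all(np.diff(e[: k + 1]) >= -1e-6)
        assert np.all(np.diff(e[k:]) <= 1e-6)


class TestHessian:
    def test_quadratic_bowl(self):
        k = 37.0
        surface = PotentialSurface(lambda x: 0.5 * k * x[0] ** 2,
                                   lambda x: np.array([k * x[0]]), dimension=1)
        h = finite_difference_hessian(surface, np.array([0.0]))
        assert h[0, 0] == pytest.approx(k, abs=1e-6)

    def test_analytic_saddle_eigenvalues(self):
        k1, k2 = 12.0, 7.0
        surface = PotentialSurface(
            lambda x: 0.5 * k1 * x[0] ** 2 - 0.5 * k2 * x[1] ** 2, dimension=2
        )
        h = finite_difference_hessian(surface, np.array([0.0, 0.0]))
        eig = np.sort(np.linalg.eigvalsh(h))
        assert eig[0] == pytest.approx(-k2, abs=1e-5)
        assert eig[1] == pytest.approx(k1, abs=1e-5)

    def test_against_symbolic_second_derivatives(self):
        x, y = sympy.symbols("x y")
        expr = 0.3 * x**3 - 1.2 * x * y**2 + 0.7 * y**3 + 2.0 * x * y
        f = sympy.lambdify((x, y), expr, "numpy")
        surface = PotentialSurface(lambda p: float(f(p[0], p[1])), dimension=2)
        point = np.array([0.4, -0.7])
        h = finite_difference_hessian(surface, point, step=1e-4)
        h_exact = np.array([
            [float(sympy.diff(expr, a, b).subs({x: point[0], y: point[1]}))
             for b in (x, y)]
            for a in (x, y)
        ])
        assert np.abs(h - h_exact).max() <= 1e-5

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            finite_difference_hessian(flat_surface(1), np.array([0.0]), step=0.0)


class TestNormalModes:
    def test_oscillator_frequency_closed_form(self):
        # independent conversion from scipy.constants, not the package constant
        import scipy.constants as c

        k, m = 100.0, 12.0
        modes = normal_modes(np.array([[k]]), np.array([m]))
        omega = math.sqrt(4184.0 * k / c.N_A / 1e-20 / (m * c.atomic_mass))
        expected_cm = omega / (2 * math.pi * c.c * 100.0)
        assert modes.frequencies[0] == pytest.approx(expected_cm, rel=1e-9)
        assert modes.n_imaginary == 0

    def test_saddle_has_one_imaginary_mode(self):
        k1, k2 = 12.0, 7.0
        h = np.diag([k1, -k2])
        modes = normal_modes(h)
        assert modes.n_imaginary == 1
        assert modes.imaginary_frequencies[0] == pytest.approx(
            FREQ_CM * math.sqrt(k2), rel=1e-9
        )

    def test_positive_definite_has_none(self):
        modes = normal_modes(np.diag([3.0, 8.0, 1.0]))
        assert modes.n_imaginary == 0

    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 4))
        modes = normal_modes(a + a.T, np.array([1.0, 12.0, 16.0, 55.0]))
        assert np.allclose(modes.eigenvectors.T @ modes.eigenvectors, np.eye(4),
                           atol=1e-10)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            normal_modes(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_reduced_mass_single_mode(self):
        modes = normal_modes(np.array([[50.0]]), np.array([7.0]))
        assert modes.reduced_masses[0] == pytest.approx(7.0)


class TestClassification:
    def test_bowl_is_minimum(self):
        assert classify_stationary_point(normal_modes(np.diag([2.0, 5.0]))) == "minimum"

    def test_saddle_along_reaction_coordinate(self):
        modes = normal_modes(np.diag([-3.0, 8.0]))
        assert classify_stationary_point(modes, np.array([0])) == "transition_state"

    def test_saddle_off_reaction_coordinate_rejected(self):
        modes = normal_modes(np.diag([-3.0, 8.0]))
        assert classify_stationary_point(modes, np.array([1])) == "higher_order_saddle"

    def test_two_negative_eigenvalues(self):
        modes = normal_modes(np.diag([-3.0, -8.0, 2.0]))
        assert classify_stationary_point(modes) == "higher_order_saddle"

    def test_invariant_under_uniform_mass_scaling(self):
        h = np.diag([-3.0, 8.0])
        for scale in (1.0, 10.0, 0.1):
            modes = normal_modes(h, np.array([12.0, 12.0]) * scale)
            assert classify_stationary_point(modes, np.array([0])) == "transition_state"


class TestDescentAndBarrier:
    def test_quartic_descent_reaches_both_minima(self):
        surface, truth = gen_double_well_surface(SurfaceSpec(barrier=5.0))
        a, b = descend_path(surface, np.array([0.0]), np.array([1.0]))
        ends = sorted([a[0], b[0]])
        assert ends[0] == pytest.approx(-1.0, abs=1e-3)
        assert ends[1] == pytest.approx(1.0, abs=1e-3)

    def test_2d_descent_matches_planted_minima(self):
        surface, truth = gen_double_well_surface(
            SurfaceSpec(kind="two_minimum_2d", grid_resolution=301)
        )
        h = finite_difference_hessian(surface, truth.saddle)
        modes = normal_modes(h)
        mode = modes.eigenvectors[:, int(np.argmin(modes.eigenvalues))]
        # displacement larger than the grid-resolution error of the saddle
        a, b = descend_path(surface, truth.saddle, mode, displacement=0.05)
        found = sorted([a, b], key=lambda p: p[0])
        planted = truth.minima[np.argsort(truth.minima[:, 0])]
        assert np.allclose(found[0], planted[0], atol=1e-2)
        assert np.allclose(found[1], planted[1], atol=1e-2)

    def test_descent_from_minimum_stays_put(self):
        surface, truth = gen_double_well_surface(SurfaceSpec(barrier=5.0))
        a, b = descend_path(surface, truth.minima[0], np.array([1.0]),
                            displacement=1e-4)
        assert a[0] == pytest.approx(truth.minima[0][0], abs=1e-3)
        assert b[0] == pytest.approx(truth.minima[0][0], abs=1e-3)

    def test_symmetric_barriers_equal(self):
        surface, truth = gen_double_well_surface(SurfaceSpec(barrier=5.0))
        res = run_neb(truth.minima[0], truth.minima[1], surface)
        assert res.barrier_forward == pytest.approx(res.barrier_reverse, abs=0.02)
        assert activation_energy(res) == pytest.approx(res.barrier_forward)

    def test_unconverged_band_warns(self):
        surface, truth = gen_double_well_surface(SurfaceSpec(barrier=5.0))
        res = run_neb(truth.minima[0], truth.minima[1], surface,
                      NebSettings(max_iterations=2))
        assert not res.converged
        with pytest.warns(UserWarning, match="unconverged"):
            activation_energy(res)
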