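"""Flow-solver contracts: exact degenerate cases, boundary conditions,
conservation, and interpolation."""

import warnings

import numpy as np
import pytest

import coralflow as cf
from coralflow.solver import (
    ConvergenceError,
    OutOfDomainError,
    SolverSettings,
    interpolate_velocity,
    solve_steady,
    solve_unsteady,
)


@pytest.fixture(scope="module")
def cell():
    return cf.make_branch_cell(2.0)


@pytest.fixture(scope="module")
def empty(cell):
    return cf.ObstacleSet(solids=(), cell=cell)


class TestDegenerateExactCases:
    def test_empty_domain_uniform_flow_is_exact(self, cell, empty):
        f = solve_steady(cell, empty, U=0.7)
        assert f.convergence["iterations"] == 1
        assert f.convergence["residual"] == 0.0
        np.testing.assert_array_equal(f.velocity[..., 0], 0.0)
        np.testing.assert_array_equal(f.velocity[..., 2], 0.0)
        np.testing.assert_array_equal(f.velocity[..., 1], 0.7)

    def test_zero_inlet_speed_gives_zero_field(self, cell):
        f = solve_steady(cell, U=0.0, settings=SolverSettings(max_iters=500))
        assert np.all(f.velocity == 0.0)

    def test_empty_domain_unsteady_matches_steady_at_all_times(self, cell, empty):
        f, rep = solve_unsteady(cell, empty, U=0.4, n_steps=4, store_every=1)
        for frame in rep["frames"]:
            np.testing.assert_allclose(frame.velocity[..., 1], 0.4, atol=1e-12)
        assert rep["steadiness"] < 1e-12

    def test_zero_inlet_unsteady_is_identically_zero(self, cell):
        f, _ = solve_unsteady(
            cell, U=0.0, total_time=0.5, n_steps=3,
            settings=SolverSettings(max_inner=30),
        )
        assert np.all(f.velocity == 0.0)


class TestSolverContracts:
    def test_velocity_zero_inside_obstacles(self, solve_cached):
        f = solve_cached("branch", 2.0, 0.8)
        assert np.all(f.velocity[f.solid] == 0.0)

    def test_mass_conservation_every_section(self, solve_cached):
        # the residual stopping point bounds the accumulated divergence: the
        # section fluxes balance to a few percent at default settings and
        # tighten to ~1% at tolerance 3e-4 (documented in the methods note)
        f = solve_cached("branch", 2.0, 0.8)
        assert f.convergence["max_flux_deviation"] < 0.1
        assert f.convergence["inlet_flux"] == pytest.approx(
            f.convergence["outlet_flux"], rel=0.08
        )

    def test_half_domain_symmetry_matches_full_solve(self, solve_cached):
        """The exported mirrored field agrees with an explicit full-height
        solve, validating the z-reflection symmetry of the steady flow."""
        half = solve_cached("branch", 2.0, 1.0)
        cell = cf.make_branch_cell(2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            full = solve_steady(
                cell, U=1.0,
                settings=SolverSettings(use_z_symmetry=False, plateau_factor=30.0),
            )
        le_half = cf.leakiness_line(half).le
        le_full = cf.leakiness_line(full).le
        assert le_half == pytest.approx(le_full, abs=0.015)
        # and the full solve itself is z-symmetric about mid-height (the
        # stretched grid is not index-symmetric, so compare by interpolation)
        cellh = full.cell
        rng = np.random.default_rng(21)
        pts = rng.uniform((0, 1.6, 0.3), (cellh.cell_width, 3.5, 1.9), size=(200, 3))
        mirrored = pts.copy()
        mirrored[:, 2] = cellh.domain_height - mirrored[:, 2]
        vy = full.interpolate(pts)[:, 1]
        vy_m = full.interpolate(mirrored)[:, 1]
        assert np.max(np.abs(vy - vy_m)) / 1.0 < 0.05  # scaled by U = 1 cm/s

    def test_nonconvergence_raises_with_history(self, cell):
        s = SolverSettings(
            max_iters=300, allow_plateau=False, coarse_init=False,
            tolerance=1e-8, div_tolerance=1e-8,
        )
        with pytest.raises(ConvergenceError) as err:
            solve_steady(cell, U=0.5, settings=s)
        assert len(err.value.residual_history) >= 1

    def test_high_re_warns(self, cell, empty):
        with pytest.warns(RuntimeWarning, match="laminar range"):
            solve_steady(cell, empty, U=30.0, settings=SolverSettings(max_iters=5))

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SolverSettings(n_per_diameter=4)
        with pytest.raises(ValueError):
            SolverSettings(tolerance=-1.0)


class TestInterpolation:
    def test_nodal_values_reproduced(self, solve_cached):
        f = solve_cached("branch", 2.0, 0.8)
        i, j, k = 5, 20, 10
        p = (f.x[i], f.y[j], f.z[k])
        np.testing.assert_allclose(
            interpolate_velocity(f, p), f.velocity[i, j, k], rtol=1e-12
        )

    def test_edge_midpoint_in_uniform_field(self, cell, empty):
        f = solve_steady(cell, empty, U=1.3)
        p = (0.5 * (f.x[2] + f.x[3]), f.y[4], f.z[7])
        np.testing.assert_allclose(
            interpolate_velocity(f, p), [0.0, 1.3, 0.0], atol=1e-12
        )

    def test_periodic_wrap_in_x(self, solve_cached):
        f = solve_cached("branch", 2.0, 0.8)
        p = (0.07, 3.0, 2.0)
        q = (0.07 + 3 * f.x_period, 3.0, 2.0)
        np.testing.assert_allclose(
            interpolate_velocity(f, p), interpolate_velocity(f, q),
            rtol=1e-9, atol=1e-12,
        )

    def test_out_of_domain_rejected(self, solve_cached):
        f = solve_cached("branch", 2.0, 0.8)
        with pytest.raises(OutOfDomainError):
            interpolate_velocity(f, (0.1, 11.0, 2.0))
        with pytest.raises(OutOfDomainError):
            interpolate_velocity(f, (0.1, 5.0, -0.5))


def test_unsteady_report_contains_steadiness():
    cell = cf.make_branch_cell(2.0)
    empty = cf.ObstacleSet(solids=(), cell=cell)
    _, rep = solve_unsteady(cell, empty, U=1.0, n_steps=3)
    assert "steadiness" in rep and rep["steadiness"] >= 0.0
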