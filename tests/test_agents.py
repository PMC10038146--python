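"""Agent transport: Euler-Maruyama stepping, capture detection, tiling."""

import math

import numpy as np
import pytest

import coralflow as cf
from coralflow.agents import (
    STATUS_ACTIVE,
    STATUS_CAPTURED,
    STATUS_EXITED,
    AgentEnsemble,
    AgentParams,
    detect_capture,
    step_agents,
    tile_field,
)
from coralflow.fixtures import make_analytic_field


@pytest.fixture(scope="module")
def cell():
    return cf.make_branch_cell(2.0)


def _uniform_field(cell, U, resolution=(24, 48, 32)):
    f = make_analytic_field("uniform", {"U": U}, cell=cell, resolution=resolution)
    return f


def exact_shadow_fraction(params: AgentParams, cell) -> float:
    """Exact capture probability for ballistic (zero-variance) transport:
    the overlap of the release sheet with the cylinder shadow strips in x
    times the z-overlap with the cylinder span."""
    x0, x1 = params.sheet_x
    w = cell.cell_width
    overlap = 0.0
    m_lo = math.floor((x0 - cell.axis_x - cell.radius) / w)
    m_hi = math.ceil((x1 - cell.axis_x + cell.radius) / w)
    for m in range(m_lo, m_hi + 1):
        c = cell.axis_x + m * w
        overlap += max(0.0, min(x1, c + cell.radius) - max(x0, c - cell.radius))
    fx = overlap / (x1 - x0)
    z0, z1 = params.sheet_z
    fz = max(0.0, min(z1, cell.z_top) - max(z0, cell.z_bottom)) / (z1 - z0)
    return fx * fz


class TestStepping:
    def test_zero_field_zero_variance_positions_frozen(self, cell):
        f = tile_field(_uniform_field(cell, 0.0), 3.6)
        f.cell = None  # no obstacles
        p = AgentParams(n_agents=50, motion_variance=0.0)
        rng = np.random.default_rng(0)
        ens = AgentEnsemble.initialize(p, rng)
        before = ens.positions.copy()
        step_agents(ens, f, p, n_steps=20, rng=rng)
        np.testing.assert_array_equal(ens.positions, before)

    def test_brownian_displacement_variance_scales_with_time(self, cell):
        f = _uniform_field(cell, 0.0, resolution=(8, 12, 8))
        f.cell = None
        n = 20000
        v = 2.5e-3
        t = 4.0
        p = AgentParams(
            n_agents=n, motion_variance=v, dt=0.01,
            sheet_x=(1.0, 1.01), sheet_y=2.0, sheet_z=(2.0, 2.01),
        )
        rng = np.random.default_rng(42)
        ens = AgentEnsemble.initialize(p, rng)
        z0 = ens.positions[:, 2].copy()
        step_agents(ens, f, p, n_steps=int(t / p.dt), rng=rng)
        var = np.var(ens.positions[:, 2] - z0)
        se = v * t * math.sqrt(2.0 / n)  # chi-square sampling error
        assert abs(var - v * t) < 4 * se

    def test_diffusivity_convention_doubles_variance_rate(self):
        a = AgentParams(motion_variance=1e-3, variance_convention="variance")
        b = AgentParams(motion_variance=1e-3, variance_convention="diffusivity")
        assert b.variance_rate == pytest.approx(2 * a.variance_rate)

    def test_geometric_shadow_capture_in_ballistic_limit(self, cell):
        """Zero-diffusion agents in uniform flow are captured iff released
        inside a cylinder shadow: exact strip-overlap oracle."""
        f = _uniform_field(cell, 0.8)
        tiled = tile_field(f, 3.6)
        p = AgentParams(n_agents=4000, motion_variance=0.0, dt=0.01)
        rng = np.random.default_rng(1)
        ens = AgentEnsemble.initialize(p, rng)
        step_agents(ens, tiled, p, n_steps=2500, rng=rng)
        frac = ens.capture_fraction
        expect = exact_shadow_fraction(p, cell)
        se = math.sqrt(expect * (1 - expect) / p.n_agents)
        assert abs(frac - expect) < 4 * se

    def test_agent_count_conserved(self, cell):
        f = _uniform_field(cell, 0.8)
        tiled = tile_field(f, 3.6)
        p = AgentParams(n_agents=500, motion_variance=2.5e-3)
        rng = np.random.default_rng(3)
        ens = AgentEnsemble.initialize(p, rng)
        step_agents(ens, tiled, p, n_steps=500, rng=rng)
        counts = {
            s: int(np.sum(ens.status == s))
            for s in (STATUS_ACTIVE, STATUS_CAPTURED, STATUS_EXITED)
        }
        assert sum(counts.values()) == 500
        assert counts[STATUS_CAPTURED] > 0

    def test_same_seed_reproduces_trajectories(self, cell):
        f = _uniform_field(cell, 0.5)
        tiled = tile_field(f, 3.6)
        p = AgentParams(n_agents=200, motion_variance=2.5e-3)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            ens = AgentEnsemble.initialize(p, rng)
            step_agents(ens, tiled, p, n_steps=300, rng=rng)
            out.append((ens.positions.copy(), ens.status.copy()))
        np.testing.assert_array_equal(out[0][0], out[1][0])
        np.testing.assert_array_equal(out[0][1], out[1][1])

    def test_large_step_warns(self, cell):
        f = _uniform_field(cell, 0.8)
        p = AgentParams(n_agents=10, motion_variance=0.0, dt=0.2)
        ens = AgentEnsemble.initialize(p, np.random.default_rng(0))
        with pytest.warns(RuntimeWarning, match="step length"):
            step_agents(ens, f, p, n_steps=1, rng=np.random.default_rng(0))


class TestDetectCapture:
    def setup_method(self):
        self.cell = cf.make_branch_cell(2.0)
        self.obs = self.cell.obstacles()

    def test_segment_wholly_outside(self):
        res = detect_capture((0.0, 0.5, 2.0), (0.0, 1.5, 2.0), self.obs)
        assert not res.captured

    def test_segment_into_cylinder_center_reports_surface_contact(self):
        start = (self.cell.axis_x, 1.5, 2.0)
        end = (self.cell.axis_x, self.cell.axis_y, 2.0)
        res = detect_capture(start, end, self.obs)
        assert res.captured
        cp = np.asarray(res.contact_point)
        r = np.hypot(cp[0] - self.cell.axis_x, cp[1] - self.cell.axis_y)
        assert r == pytest.approx(self.cell.radius, abs=1e-6)

    @pytest.mark.parametrize("offset, expected", [(-1e-6, True), (1e-4, False)])
    def test_grazing_tangent(self, offset, expected):
        """A tangent segment at R -+ epsilon, cross-checked against a dense
        subdivision oracle."""
        x_graze = self.cell.axis_x + self.cell.radius + offset
        start = (x_graze, 1.0, 2.0)
        end = (x_graze, 3.0, 2.0)
        res = detect_capture(start, end, self.obs, tol=1e-9)
        assert res.captured == expected
        ts = np.linspace(0, 1, 20001)
        pts = np.asarray(start) + ts[:, None] * (np.asarray(end) - np.asarray(start))
        brute = bool(np.min(self.obs.sdf(pts)) <= 1e-9)
        assert res.captured == brute

    def test_periodic_image_contact(self):
        # a segment crossing the neighbouring cell's cylinder image
        w = self.cell.cell_width
        start = (self.cell.axis_x + w, 1.5, 2.0)
        end = (self.cell.axis_x + w, 2.5, 2.0)
        assert detect_capture(start, end, self.obs).captured

    def test_capsule_contact(self):
        obs = cf.make_polyp_cylinder(self.cell)
        # dive vertically onto the upstream polyp at the second row height
        zp = self.cell.z_bottom + self.cell.height * 3 / 8
        start = (self.cell.axis_x, self.cell.axis_y - 0.08, zp + 0.3)
        end = (self.cell.axis_x, self.cell.axis_y - 0.08, zp)
        res = detect_capture(start, end, obs)
        assert res.captured


class TestTiling:
    @pytest.mark.parametrize(
        "g_over_d, target, n_expected, width_expected",
        [(1.0, 3.6, 18, 3.6), (8.0, 3.6, 4, 3.6), (2.0, 3.6, 12, 3.6)],
    )
    def test_tile_counts(self, g_over_d, target, n_expected, width_expected):
        c = cf.make_branch_cell(g_over_d)
        f = make_analytic_field("uniform", {"U": 1.0}, cell=c, resolution=(8, 8, 8))
        tiled = tile_field(f, target)
        assert tiled.n_tiles == n_expected
        assert tiled.x_period == pytest.approx(width_expected)

    def test_tiled_field_is_periodic(self, cell, solve_cached):
        f = solve_cached("branch", 2.0, 0.8)
        tiled = tile_field(f, 3.6)
        pts = np.array([[0.11, 2.5, 2.1], [0.11 + f.x_period, 2.5, 2.1]])
        v = tiled.interpolate(pts)
        np.testing.assert_allclose(v[0], v[1], rtol=1e-12)

    def test_below_one_tile_rejected(self, cell):
        f = make_analytic_field("uniform", {"U": 1.0}, cell=cell, resolution=(8, 8, 8))
        with pytest.raises(ValueError):
            tile_field(f, 0.1)


def test_params_validation():
    with pytest.raises(ValueError):
        AgentParams(motion_variance=-1.0)
    with pytest.raises(ValueError):
        AgentParams(dt=0.0)
    with pytest.raises(ValueError):
        AgentParams(n_agents=0)
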