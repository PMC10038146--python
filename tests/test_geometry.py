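"""Unit-cell constructors, polyp decoration, and signed-distance queries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coralflow as cf
from coralflow.geometry import GeometryError, locate


@pytest.mark.parametrize(
    "maker, g_over_d, expected_width",
    [
        (cf.make_branch_cell, 0.5, 0.15),
        (cf.make_branch_cell, 8.0, 0.9),
        (cf.make_branch_cell, 1.0, 0.2),
        (cf.make_tentacle_cell, 1.5, 0.0625),
        (cf.make_tentacle_cell, 3.0, 0.1),
        (cf.make_tentacle_cell, 2.0, 0.075),
        (cf.make_pinnule_cell, 1.25, 0.005625),  # 0.05625 mm in cm
        (cf.make_pinnule_cell, 2.5, 0.00875),
        (cf.make_pinnule_cell, 2.0, 0.0075),
    ],
)
def test_cell_widths_match_study_domains(maker, g_over_d, expected_width):
    cell = maker(g_over_d)
    assert cell.cell_width == pytest.approx(expected_width, rel=1e-12)
    # exact identity, not approximate: width is defined as D + G
    assert cell.cell_width - (cell.diameter + cell.gap) == 0.0


@pytest.mark.parametrize(
    "maker, bad",
    [
        (cf.make_branch_cell, 0.0),
        (cf.make_branch_cell, -1.0),
        (cf.make_branch_cell, 11.0),
        (cf.make_tentacle_cell, 0.5),
        (cf.make_pinnule_cell, 6.0),
    ],
)
def test_invalid_ratio_rejected(maker, bad):
    with pytest.raises(ValueError):
        maker(bad)


def test_scale_presets():
    b = cf.make_branch_cell(2.0)
    assert (b.diameter, b.height) == (0.1, 1.0)
    assert (b.domain_length, b.domain_height) == (10.0, 4.0)
    assert b.cylinder_inlet_offset == 2.0
    t = cf.make_tentacle_cell(2.0)
    assert (t.diameter, t.height, t.domain_length) == (0.025, 0.25, 2.5)
    p = cf.make_pinnule_cell(2.0)
    assert (p.diameter, p.height, p.domain_length) == (0.0025, 0.025, 0.25)
    assert p.h_over_d == pytest.approx(10.0)


class TestPolypDecoration:
    def test_solid_count(self):
        cell = cf.make_branch_cell(2.0)
        obs = cf.make_polyp_cylinder(cell)
        # 1 cylinder + 2 sides x 4 polyps x (1 stalk + 8 tentacles)
        assert len(obs.solids) == 73

    def test_no_polyps_degenerates_to_plain_cylinder(self):
        cell = cf.make_branch_cell(2.0)
        obs = cf.make_polyp_cylinder(cell, cf.PolypModel(polyps_per_side=0))
        assert len(obs.solids) == 1

    def test_axis_point_inside(self):
        cell = cf.make_branch_cell(2.0)
        obs = cf.make_polyp_cylinder(cell)
        res = locate((cell.axis_x, cell.axis_y, cell.z_mid), obs)
        assert res.inside

    def test_periodic_overlap_rejected(self):
        with pytest.raises(GeometryError):
            cf.make_polyp_cylinder(cf.make_branch_cell(0.3))

    def test_reflection_symmetry_through_axis_plane(self):
        """The polyp set is mirror-symmetric in x about the cylinder axis."""
        cell = cf.make_branch_cell(2.0)
        obs = cf.make_polyp_cylinder(cell)
        rng = np.random.default_rng(7)
        pts = rng.uniform(
            (0, 1.8, 1.4), (cell.cell_width, 2.4, 2.6), size=(200, 3)
        )
        mirrored = pts.copy()
        mirrored[:, 0] = 2 * cell.axis_x - mirrored[:, 0]
        np.testing.assert_allclose(obs.sdf(pts), obs.sdf(mirrored), atol=1e-10)

    def test_total_height_matches_model(self):
        m = cf.PolypModel()
        axial = m.stalk_length + m.tentacle_length * math.cos(
            math.radians(m.splay_deg)
        ) + m.tentacle_diameter / 2.0
        assert axial == pytest.approx(m.polyp_height)


class TestLocate:
    def setup_method(self):
        self.cell = cf.make_branch_cell(2.0)
        self.obs = self.cell.obstacles()

    def test_cylinder_center(self):
        res = locate((self.cell.axis_x, self.cell.axis_y, self.cell.z_mid), self.obs)
        assert res.inside
        assert res.surface_distance == pytest.approx(-self.cell.radius)

    def test_point_one_diameter_from_axis(self):
        p = (self.cell.axis_x + self.cell.diameter, self.cell.axis_y, self.cell.z_mid)
        res = locate(p, self.obs)
        assert not res.inside
        assert res.surface_distance == pytest.approx(self.cell.radius)

    def test_point_above_tip_on_axis(self):
        """Closed-form distance above the flat cap, checked against a dense
        surface-sampling oracle."""
        h = 0.07
        p = np.array([self.cell.axis_x, self.cell.axis_y, self.cell.z_top + h])
        res = locate(p, self.obs)
        assert not res.inside
        assert res.surface_distance == pytest.approx(h, rel=1e-12)
        # brute force: minimum distance to densely sampled surface points
        cyl = self.cell.cylinder()
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        zs = np.linspace(cyl.z0, cyl.z1, 400)
        ring = np.stack(
            [
                cyl.center_x + cyl.radius * np.cos(theta),
                cyl.center_y + cyl.radius * np.sin(theta),
            ],
            axis=1,
        )
        side = np.concatenate(
            [np.column_stack([ring, np.full(len(ring), z)]) for z in zs[:: 40]]
        )
        rr = np.linspace(0, cyl.radius, 200)
        cap = np.column_stack(
            [cyl.center_x + rr, np.full(len(rr), cyl.center_y), np.full(len(rr), cyl.z1)]
        )
        brute = min(
            np.min(np.linalg.norm(side - p, axis=1)),
            np.min(np.linalg.norm(cap - p, axis=1)),
        )
        assert res.surface_distance == pytest.approx(brute, abs=1e-3)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        x=st.floats(0.0, 0.3),
        y=st.floats(1.5, 3.0),
        z=st.floats(0.5, 3.5),
        shift=st.integers(-3, 3),
    )
    def test_periodic_wrap_invariance(self, x, y, z, shift):
        p = (x, y, z)
        q = (x + shift * self.cell.cell_width, y, z)
        a = locate(p, self.obs)
        b = locate(q, self.obs)
        assert a.inside == b.inside
        assert a.surface_distance == pytest.approx(b.surface_distance, abs=1e-9)

    def test_inside_iff_nonpositive_distance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform((0, 0, 0), (0.3, 10, 4), size=(500, 3))
        d = self.obs.sdf(pts)
        inside = self.obs.contains(pts)
        assert np.array_equal(inside, d <= 0)


def test_fluid_properties_consistency():
    f = cf.SEAWATER
    assert f.kinematic_viscosity == pytest.approx(f.dynamic_viscosity / f.density)
    with pytest.raises(ValueError):
        cf.FluidProperties(density=-1.0)


def test_cell_serialization_round_trip():
    cell = cf.make_tentacle_cell(2.5)
    again = cf.CylinderArrayCell.from_dict(cell.to_dict())
    assert again == cell


def test_stl_export_writes_ascii_surface(tmp_path):
    cell = cf.make_branch_cell(2.0)
    obs = cf.make_polyp_cylinder(cell, cf.PolypModel(polyps_per_side=1))
    out = tmp_path / "obstacles.stl"
    from coralflow.geometry import export_stl

    export_stl(obs, out, sections=8)
    text = out.read_text()
    assert text.startswith("solid")
    assert "facet normal" in text
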