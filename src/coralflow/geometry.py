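"""Periodic unit-cell geometry for cylinder-array models of gorgonian structures.

A gorgonian colony is idealized, level by level, as an infinite planar array of
finite-height circular cylinders: branches (diameter ~1 mm), polyp tentacles
(~0.25 mm) and tentacle pinnules (~25 um).  One cylinder sits in a periodic
"unit cell" whose width is the centre-to-centre spacing ``D + G``; side faces
are periodic so the cell tiles into an infinite row normal to the oncoming
flow.

Coordinate convention (all lengths in cm internally):

* ``x`` — periodic direction, across the gaps between cylinders,
* ``y`` — streamwise, inlet at ``y = 0``,
* ``z`` — cylinder axis, symmetry (free-slip) faces at top and bottom.

The module also builds the polyp-decorated branch: eight idealized polyps
(four per upstream/downstream face), each a short stalk carrying eight solid
tentacle capsules splayed around the oral axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "FluidProperties",
    "SEAWATER",
    "CylinderArrayCell",
    "PolypModel",
    "FiniteCylinder",
    "Capsule",
    "ObstacleSet",
    "LocateResult",
    "make_branch_cell",
    "make_tentacle_cell",
    "make_pinnule_cell",
    "make_polyp_cylinder",
    "locate",
]

ScaleLevel = Literal["branch", "tentacle", "pinnule"]


class GeometryError(ValueError):
    """Raised when a requested geometry is inconsistent (overlaps, bad ratios)."""


@dataclass(frozen=True)
class FluidProperties:
    """Fluid constants used by the solver and for Reynolds-number labelling.

    Parameters
    ----------
    density : float
        Mass density ``rho`` in g cm^-3.
    dynamic_viscosity : float
        Dynamic viscosity ``mu`` in poise (g cm^-1 s^-1).
    nominal_kinematic_viscosity : float
        The rounded kinematic viscosity (cm^2 s^-1) used to label integer
        Reynolds numbers (``Re = U D / nu_nominal``); the solver itself always
        uses the true ``mu`` and ``rho``.
    """

    density: float = 1.025
    dynamic_viscosity: float = 0.0108
    nominal_kinematic_viscosity: float = 0.01

    def __post_init__(self) -> None:
        for name in ("density", "dynamic_viscosity", "nominal_kinematic_viscosity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def kinematic_viscosity(self) -> float:
        """True kinematic viscosity ``mu / rho`` in cm^2 s^-1."""
        return self.dynamic_viscosity / self.density


#: Seawater at the conditions used throughout the study.
SEAWATER = FluidProperties()


@dataclass(frozen=True)
class CylinderArrayCell:
    """One periodic cell of an infinite cylinder array at a given scale level.

    All lengths are stored in cm regardless of the natural unit of the scale
    level (pinnule inputs are converted from mm on construction).  The cylinder
    axis is vertical (``z``), centred across the cell width and centred
    vertically in the domain.
    """

    scale_level: ScaleLevel
    diameter: float
    height: float
    gap: float
    domain_length: float
    domain_height: float
    cylinder_inlet_offset: float
    boundary_roles: dict = field(
        default_factory=lambda: {
            "y_min": "inlet",
            "y_max": "outlet",
            "x_min": "periodic",
            "x_max": "periodic",
            "z_min": "symmetry",
            "z_max": "symmetry",
        }
    )

    def __post_init__(self) -> None:
        if min(self.diameter, self.height, self.gap) <= 0:
            raise ValueError("diameter, height and gap must be strictly positive")
        if self.cylinder_inlet_offset + self.radius >= self.domain_length:
            raise GeometryError("cylinder does not fit inside the domain (streamwise)")
        if self.height >= self.domain_height:
            raise GeometryError("cylinder does not fit inside the domain (vertical)")

    # -- derived quantities -------------------------------------------------
    @property
    def cell_width(self) -> float:
        """Periodic cell width ``D + G`` (centre-to-centre cylinder spacing)."""
        return self.diameter + self.gap

    @property
    def g_over_d(self) -> float:
        return self.gap / self.diameter

    @property
    def h_over_d(self) -> float:
        return self.height / self.diameter

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def axis_x(self) -> float:
        return self.cell_width / 2.0

    @property
    def axis_y(self) -> float:
        return self.cylinder_inlet_offset

    @property
    def z_bottom(self) -> float:
        return (self.domain_height - self.height) / 2.0

    @property
    def z_top(self) -> float:
        return (self.domain_height + self.height) / 2.0

    @property
    def z_mid(self) -> float:
        return self.domain_height / 2.0

    def cylinder(self) -> "FiniteCylinder":
        """The central cylinder as an analytic solid."""
        return FiniteCylinder(
            center_x=self.axis_x,
            center_y=self.axis_y,
            z0=self.z_bottom,
            z1=self.z_top,
            radius=self.radius,
        )

    def obstacles(self) -> "ObstacleSet":
        """Obstacle set holding just the plain central cylinder."""
        return ObstacleSet(solids=(self.cylinder(),), cell=self)

    def to_dict(self) -> dict:
        return {
            "scale_level": self.scale_level,
            "diameter": self.diameter,
            "height": self.height,
            "gap": self.gap,
            "domain_length": self.domain_length,
            "domain_height": self.domain_height,
            "cylinder_inlet_offset": self.cylinder_inlet_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CylinderArrayCell":
        return cls(**d)


_SCALE_PRESETS = {
    # level: (D, H, domain_length, domain_height, inlet_offset)  [cm]
    "branch": (0.1, 1.0, 10.0, 4.0, 2.0),
    "tentacle": (0.025, 0.25, 2.5, 1.0, 0.5),
    # pinnule preset given in mm in its natural unit; converted below
    "pinnule": (0.0025, 0.025, 0.25, 0.10, 0.05),
}


def make_branch_cell(g_over_d: float) -> CylinderArrayCell:
    """Branch-level cell: D=0.1 cm, H=1 cm, domain 10 x 4 cm, cylinder 2 cm in."""
    if not 0 < g_over_d <= 10:
        raise ValueError(f"branch gap-to-diameter ratio must lie in (0, 10], got {g_over_d}")
    d, h, length, height, offset = _SCALE_PRESETS["branch"]
    return CylinderArrayCell(
        scale_level="branch",
        diameter=d,
        height=h,
        gap=g_over_d * d,
        domain_length=length,
        domain_height=height,
        cylinder_inlet_offset=offset,
    )


def make_tentacle_cell(g_over_d: float) -> CylinderArrayCell:
    """Tentacle-level cell: D=0.025 cm, H=0.25 cm, domain 2.5 x 1.0 cm."""
    if not 1 <= g_over_d <= 5:
        raise ValueError(f"tentacle gap-to-diameter ratio must lie in [1, 5], got {g_over_d}")
    d, h, length, height, offset = _SCALE_PRESETS["tentacle"]
    return CylinderArrayCell(
        scale_level="tentacle",
        diameter=d,
        height=h,
        gap=g_over_d * d,
        domain_length=length,
        domain_height=height,
        cylinder_inlet_offset=offset,
    )


def make_pinnule_cell(g_over_d: float) -> CylinderArrayCell:
    """Pinnule-level cell: D=0.025 mm, H=0.25 mm, domain 2.5 x 1.0 mm.

    Inputs are the natural mm values of the pinnule scale; the stored cell is
    in cm like every other scale.
    """
    if not 1 <= g_over_d <= 5:
        raise ValueError(f"pinnule gap-to-diameter ratio must lie in [1, 5], got {g_over_d}")
    d, h, length, height, offset = _SCALE_PRESETS["pinnule"]
    return CylinderArrayCell(
        scale_level="pinnule",
        diameter=d,
        height=h,
        gap=g_over_d * d,
        domain_length=length,
        domain_height=height,
        cylinder_inlet_offset=offset,
    )


# ---------------------------------------------------------------------------
# Analytic solids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FiniteCylinder:
    """Finite circular cylinder with axis parallel to z (flat caps)."""

    center_x: float
    center_y: float
    z0: float
    z1: float
    radius: float

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance (negative inside) at an (n, 3) array of points."""
        pts = np.atleast_2d(pts)
        dr = np.hypot(pts[:, 0] - self.center_x, pts[:, 1] - self.center_y) - self.radius
        dz = np.maximum(self.z0 - pts[:, 2], pts[:, 2] - self.z1)
        inside = np.maximum(dr, dz)
        outside = np.hypot(np.maximum(dr, 0.0), np.maximum(dz, 0.0))
        return np.where((dr <= 0) & (dz <= 0), inside, outside)

    @property
    def bounding_radius_xy(self) -> float:
        return self.radius

    def bbox(self) -> tuple:
        return (
            self.center_x - self.radius,
            self.center_x + self.radius,
            self.center_y - self.radius,
            self.center_y + self.radius,
            self.z0,
            self.z1,
        )


@dataclass(frozen=True)
class Capsule:
    """Capsule (cylinder with spherical end caps) between two points."""

    p0: tuple
    p1: tuple
    radius: float

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        a = np.asarray(self.p0, dtype=float)
        b = np.asarray(self.p1, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        ap = pts - a
        if denom == 0.0:
            return np.linalg.norm(ap, axis=1) - self.radius
        t = np.clip((ap @ ab) / denom, 0.0, 1.0)
        closest = a + t[:, None] * ab
        return np.linalg.norm(pts - closest, axis=1) - self.radius

    def bbox(self) -> tuple:
        lo = np.minimum(self.p0, self.p1) - self.radius
        hi = np.maximum(self.p0, self.p1) + self.radius
        return (lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])


@dataclass(frozen=True)
class LocateResult:
    inside: bool
    surface_distance: float  # signed, negative inside


@dataclass(frozen=True)
class ObstacleSet:
    """Collection of analytic solids inside one periodic cell.

    The signed-distance query accounts for the periodic images in x, so a
    point near the cell edge sees the neighbouring cylinder's polyps too.
    """

    solids: tuple
    cell: CylinderArrayCell

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance to the union of solids (periodic in x)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if not self.solids:
            return np.full(pts.shape[0], np.inf)
        w = self.cell.cell_width
        # wrap x into [0, w) then consider the -w and +w images
        wrapped = pts.copy()
        wrapped[:, 0] = np.mod(wrapped[:, 0], w)
        best = np.full(pts.shape[0], np.inf)
        for shift in (-w, 0.0, w):
            shifted = wrapped.copy()
            shifted[:, 0] += shift
            for solid in self.solids:
                np.minimum(best, solid.sdf(shifted), out=best)
        return best

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.sdf(pts) <= 0.0

    def mask(self, xc: np.ndarray, yc: np.ndarray, zc: np.ndarray,
             inflate: float = 0.0) -> np.ndarray:
        """Boolean solid mask on the tensor grid of cell centres.

        ``inflate`` > 0 marks cells whose centre lies within that distance of
        a surface as solid; used to keep features thinner than the local grid
        spacing watertight under stair-step masking.
        """
        X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        d = self.sdf(pts)
        return (d <= inflate).reshape(X.shape)

    def is_empty(self) -> bool:
        return len(self.solids) == 0

    def bbox(self) -> tuple | None:
        """Axis-aligned bounding box of all solids, or None when empty."""
        if not self.solids:
            return None
        boxes = np.array([s.bbox() for s in self.solids])
        return (
            boxes[:, 0].min(), boxes[:, 1].max(),
            boxes[:, 2].min(), boxes[:, 3].max(),
            boxes[:, 4].min(), boxes[:, 5].max(),
        )


@dataclass(frozen=True)
class PolypModel:
    """Idealized polyp used to decorate a branch cylinder.

    Eight solid tentacles of length ``tentacle_length`` rest on a short stalk;
    stalk length is chosen so the whole polyp stands ``polyp_height`` proud of
    the cylinder surface.  Tentacles splay at ``splay_deg`` degrees from the
    oral axis (the outward surface normal), evenly spaced in azimuth.
    """

    polyps_per_side: int = 4
    tentacles_per_polyp: int = 8
    tentacle_length: float = 0.1  # cm
    polyp_height: float = 0.09  # cm, total stand-off from the cylinder surface
    tentacle_diameter: float = 0.0125  # cm
    stalk_diameter: float = 0.03  # cm
    splay_deg: float = 45.0

    @property
    def stalk_length(self) -> float:
        axial = self.tentacle_length * math.cos(math.radians(self.splay_deg))
        s = self.polyp_height - axial - self.tentacle_diameter / 2.0
        if s <= 0:
            raise GeometryError(
                "polyp_height too small for the requested tentacle length/splay"
            )
        return s

    @property
    def lateral_extent(self) -> float:
        """Maximum reach of a tentacle normal to the oral axis."""
        return (
            self.tentacle_length * math.sin(math.radians(self.splay_deg))
            + self.tentacle_diameter / 2.0
        )


def make_polyp_cylinder(cell: CylinderArrayCell, model: PolypModel | None = None) -> ObstacleSet:
    """Decorate the cell's cylinder with idealized polyps.

    Polyps sit on the two cylinder faces normal to the incident flow (the
    upstream and downstream sides), ``polyps_per_side`` per face, with centres
    evenly spaced along the cylinder height at fractions (2i+1)/(2n) of H.
    Raises :class:`GeometryError` if a tentacle would overlap the periodic
    image of a neighbouring polyp.
    """
    if model is None:
        model = PolypModel()
    if cell.scale_level != "branch":
        raise GeometryError("polyp decoration is defined for branch-scale cells")
    solids: list = [cell.cylinder()]
    if model.polyps_per_side == 0:
        return ObstacleSet(solids=tuple(solids), cell=cell)
    if cell.axis_x + model.lateral_extent >= cell.cell_width:
        raise GeometryError("polyps overlap their periodic images at this G/D")
    splay = math.radians(model.splay_deg)
    n = model.polyps_per_side
    z_centers = [cell.z_bottom + cell.height * (2 * i + 1) / (2 * n) for i in range(n)]
    for side in (-1.0, 1.0):  # upstream (-y) and downstream (+y) faces
        normal = np.array([0.0, side, 0.0])
        for zc in z_centers:
            base = np.array([cell.axis_x, cell.axis_y + side * cell.radius, zc])
            tip = base + normal * model.stalk_length
            solids.append(Capsule(tuple(base), tuple(tip), model.stalk_diameter / 2.0))
            for k in range(model.tentacles_per_polyp):
                phi = 2.0 * math.pi * k / model.tentacles_per_polyp
                lateral = np.array([math.cos(phi), 0.0, math.sin(phi)])
                direction = math.cos(splay) * normal + math.sin(splay) * lateral
                end = tip + direction * model.tentacle_length
                solids.append(
                    Capsule(tuple(tip), tuple(end), model.tentacle_diameter / 2.0)
                )
    return ObstacleSet(solids=tuple(solids), cell=cell)


def locate(point: Sequence[float], obstacles: ObstacleSet) -> LocateResult:
    """Classify a point against an obstacle set (periodic in x).

    Returns the signed surface distance: negative inside a solid, positive in
    the fluid; consistent across periodic images.
    """
    d = float(obstacles.sdf(np.asarray(point, dtype=float)[None, :])[0])
    return LocateResult(inside=d <= 0.0, surface_distance=d)


def export_stl(obstacles: ObstacleSet, path: str, sections: int = 32) -> None:
    """Write the obstacle surfaces as an ASCII STL for visualization."""
    import trimesh

    meshes = []
    for s in obstacles.solids:
        if isinstance(s, FiniteCylinder):
            m = trimesh.creation.cylinder(radius=s.radius, height=s.z1 - s.z0, sections=sections)
            m.apply_translation([s.center_x, s.center_y, (s.z0 + s.z1) / 2.0])
        elif isinstance(s, Capsule):
            a = np.asarray(s.p0)
            b = np.asarray(s.p1)
            h = float(np.linalg.norm(b - a))
            m = trimesh.creation.capsule(radius=s.radius, height=max(h, 1e-9), count=[8, 8])
            # capsule is built along +z from origin; align to the segment
            T = trimesh.geometry.align_vectors([0, 0, 1], (b - a) / max(h, 1e-12))
            m.apply_transform(T)
            m.apply_translation((a + b) / 2.0)
        else:  # pragma: no cover - no other solid types exist
            continue
        meshes.append(m)
    combined = trimesh.util.concatenate(meshes)
    combined.export(path, file_type="stl_ascii")
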