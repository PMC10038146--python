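"""Field/table readers and writers, run configuration, and the run driver.

CSV is the canonical tabular format (units recorded in ``#`` header
comments); HDF5 is the archival field format and legacy-ASCII VTK
rectilinear-grid files are written for visualization.  Every artifact
records the package version, the configuration hash and the seed so a run
is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import CylinderArrayCell, FluidProperties, SEAWATER
from .solver import FlowField, SolverSettings, solve_steady

__all__ = [
    "FormatError",
    "write_field",
    "read_field",
    "write_field_vtk",
    "read_field_vtk",
    "write_table",
    "RunConfig",
    "run",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed or truncated field file."""


def _version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# HDF5 fields
# ---------------------------------------------------------------------------


def write_field(field: FlowField, path: str | Path, seed: int | None = None,
                config_hash: str = "") -> None:
    """Write a FlowField to HDF5 (lossless round-trip of grid and metadata)."""
    import h5py

    with h5py.File(path, "w") as h5:
        for name in ("x", "y", "z"):
            h5.create_dataset(name, data=getattr(field, name))
        h5.create_dataset("velocity", data=field.velocity, compression="gzip")
        h5.create_dataset("pressure", data=field.pressure, compression="gzip")
        h5.create_dataset("solid", data=field.solid.astype(np.uint8), compression="gzip")
        h5.attrs["units_length"] = "cm"
        h5.attrs["units_velocity"] = "cm/s"
        h5.attrs["axis_order"] = "x (periodic), y (streamwise), z (cylinder axis)"
        h5.attrs["inlet_speed"] = field.inlet_speed
        h5.attrs["x_period"] = field.x_period
        h5.attrs["n_tiles"] = field.n_tiles
        h5.attrs["version"] = _version()
        h5.attrs["config_hash"] = config_hash
        if seed is not None:
            h5.attrs["seed"] = seed
        if field.cell is not None:
            h5.attrs["cell"] = json.dumps(field.cell.to_dict())
        if field.fluid is not None:
            h5.attrs["fluid"] = json.dumps(
                {
                    "density": field.fluid.density,
                    "dynamic_viscosity": field.fluid.dynamic_viscosity,
                    "nominal_kinematic_viscosity": field.fluid.nominal_kinematic_viscosity,
                }
            )
        safe = {
            k: v
            for k, v in field.convergence.items()
            if isinstance(v, (int, float, bool, str))
        }
        h5.attrs["convergence"] = json.dumps(safe)


def read_field(path: str | Path) -> FlowField:
    """Read a FlowField written by :func:`write_field`.

    Obstacle geometry is reconstructed from the stored cell metadata as the
    plain central cylinder; decorated obstacle sets are not serialized.
    """
    import h5py

    try:
        with h5py.File(path, "r") as h5:
            required = {"x", "y", "z", "velocity", "pressure", "solid"}
            missing = required - set(h5.keys())
            if missing:
                raise FormatError(f"{path}: missing datasets {sorted(missing)}")
            cell = None
            if "cell" in h5.attrs:
                cell = CylinderArrayCell.from_dict(json.loads(h5.attrs["cell"]))
            fluid = None
            if "fluid" in h5.attrs:
                fluid = FluidProperties(**json.loads(h5.attrs["fluid"]))
            field = FlowField(
                x=h5["x"][:],
                y=h5["y"][:],
                z=h5["z"][:],
                velocity=h5["velocity"][:],
                pressure=h5["pressure"][:],
                solid=h5["solid"][:].astype(bool),
                inlet_speed=float(h5.attrs["inlet_speed"]),
                x_period=float(h5.attrs["x_period"]),
                n_tiles=int(h5.attrs.get("n_tiles", 1)),
                cell=cell,
                fluid=fluid,
                convergence=json.loads(h5.attrs.get("convergence", "{}")),
                obstacles=cell.obstacles() if cell is not None else None,
            )
            return field
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 field file ({exc})") from exc


# ---------------------------------------------------------------------------
# VTK legacy ASCII rectilinear grids
# ---------------------------------------------------------------------------


def write_field_vtk(field: FlowField, path: str | Path) -> None:
    """Write the field as a legacy-ASCII VTK rectilinear grid (point data)."""
    nx, ny, nz = field.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(
            f"coralflow field; units cm, cm/s; U={field.inlet_speed}; "
            f"version={_version()}\n"
        )
        fh.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        for name, coords in (("X", field.x), ("Y", field.y), ("Z", field.z)):
            fh.write(f"{name}_COORDINATES {len(coords)} double\n")
            fh.write(" ".join(f"{c:.10g}" for c in coords) + "\n")
        npts = nx * ny * nz
        fh.write(f"POINT_DATA {npts}\n")
        fh.write("VECTORS velocity double\n")
        # VTK expects x fastest; our arrays are (x, y, z) C-ordered (z fastest)
        vel = np.transpose(field.velocity, (2, 1, 0, 3)).reshape(-1, 3)
        for row in vel:
            fh.write(f"{row[0]:.10g} {row[1]:.10g} {row[2]:.10g}\n")
        fh.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
        pres = np.transpose(field.pressure, (2, 1, 0)).ravel()
        fh.write("\n".join(f"{v:.10g}" for v in pres) + "\n")
        fh.write("SCALARS solid int 1\nLOOKUP_TABLE default\n")
        sol = np.transpose(field.solid.astype(int), (2, 1, 0)).ravel()
        fh.write("\n".join(str(v) for v in sol) + "\n")


def read_field_vtk(path: str | Path) -> FlowField:
    """Read a legacy-ASCII VTK rectilinear grid written by write_field_vtk."""
    try:
        with open(path) as fh:
            lines = fh.read().split("\n")
    except OSError as exc:
        raise FormatError(f"{path}: unreadable ({exc})") from exc
    try:
        idx = 0

        def seek(prefix: str) -> list[str]:
            nonlocal idx
            while idx < len(lines):
                line = lines[idx]
                idx += 1
                if line.startswith(prefix):
                    return line.split()
            raise FormatError(f"{path}: missing section {prefix!r}")

        title = lines[1] if len(lines) > 1 else ""
        u_inlet = 0.0
        for tok in title.replace(";", " ").split():
            if tok.startswith("U="):
                u_inlet = float(tok[2:])
        dims = seek("DIMENSIONS")
        nx, ny, nz = int(dims[1]), int(dims[2]), int(dims[3])
        coords = {}
        for name in ("X", "Y", "Z"):
            n = int(seek(f"{name}_COORDINATES")[1])
            vals: list[float] = []
            while len(vals) < n:
                vals.extend(float(v) for v in lines[idx].split())
                idx += 1
            coords[name] = np.array(vals)
        seek("VECTORS")
        nvals = nx * ny * nz
        flat: list[float] = []
        while len(flat) < 3 * nvals:
            flat.extend(float(v) for v in lines[idx].split())
            idx += 1
        vel = np.array(flat).reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3)
        seek("SCALARS pressure")
        seek("LOOKUP_TABLE")
        pvals: list[float] = []
        while len(pvals) < nvals:
            pvals.extend(float(v) for v in lines[idx].split())
            idx += 1
        pres = np.array(pvals).reshape(nz, ny, nx).transpose(2, 1, 0)
        seek("SCALARS solid")
        seek("LOOKUP_TABLE")
        svals: list[float] = []
        while len(svals) < nvals:
            svals.extend(float(v) for v in lines[idx].split())
            idx += 1
        solid = np.array(svals).reshape(nz, ny, nx).transpose(2, 1, 0).astype(bool)
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: truncated or malformed near line {idx}") from exc
    dx = coords["X"][1] - coords["X"][0] if nx > 1 else 1.0
    return FlowField(
        x=coords["X"],
        y=coords["Y"],
        z=coords["Z"],
        velocity=vel,
        pressure=pres,
        solid=solid,
        inlet_speed=u_inlet,
        x_period=coords["X"][-1] + dx if nx > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# tables and config
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, units: dict | None = None,
                seed: int | None = None, config_hash: str = "") -> None:
    """CSV with provenance and column units in '#' header comments."""
    with open(path, "w") as fh:
        fh.write(f"# coralflow {_version()}; config_hash={config_hash}; seed={seed}\n")
        if units:
            fh.write("# units: " + ", ".join(f"{k}={v}" for k, v in units.items()) + "\n")
        df.to_csv(fh, index=False)


class RunConfig:
    """Validated, serializable description of one pipeline run.

    A run is reproducible from its config plus seed alone: the config stores
    the scale level, the G/D and speed grids, solver/agent parameter
    overrides, the metric selection and the output directory.
    """

    _FIELDS = (
        "scale_level", "g_over_d", "U", "nominal_re", "metrics",
        "solver", "agents", "capture", "outdir", "seed",
    )

    def __init__(
        self,
        scale_level: str = "branch",
        g_over_d: Sequence[float] = (2.0,),
        U: Sequence[float] | None = None,
        nominal_re: Sequence[float] | None = None,
        metrics: Sequence[str] = ("gap_flux", "line_average"),
        solver: dict | None = None,
        agents: dict | None = None,
        capture: bool = False,
        outdir: str = "coralflow_run",
        seed: int = 0,
    ):
        if scale_level not in ("branch", "tentacle", "pinnule"):
            raise ValueError(f"invalid scale_level {scale_level!r}")
        if (U is None) == (nominal_re is None):
            raise ValueError("give exactly one of U or nominal_re")
        if not g_over_d:
            raise ValueError("g_over_d grid is empty")
        bad = set(metrics) - {"gap_flux", "line_average"}
        if bad:
            raise ValueError(f"unknown metrics {sorted(bad)}")
        self.scale_level = scale_level
        self.g_over_d = list(g_over_d)
        self.U = list(U) if U is not None else None
        self.nominal_re = list(nominal_re) if nominal_re is not None else None
        self.metrics = list(metrics)
        self.solver = dict(solver or {})
        self.agents = dict(agents or {})
        self.capture = bool(capture)
        self.outdir = str(outdir)
        self.seed = int(seed)
        # fail early on bad overrides
        SolverSettings(**self.solver)
        if self.agents:
            from .agents import AgentParams

            AgentParams(**self.agents)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls._FIELDS)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Hash of the scientific configuration (the output path is excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run(config: RunConfig, fluid: FluidProperties = SEAWATER) -> Path:
    """Execute a configured run and write its artifact directory.

    Produces per-point HDF5 and VTK fields, a leakiness sweep CSV, a capture
    CSV when agents are enabled, a log file, plots and the resolved config.
    """
    from .agents import AgentParams, capture_table, run_capture_experiment

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("coralflow")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("run %s starting (seed %d)", chash, config.seed)
        settings = SolverSettings(**config.solver)
        from .leakiness import _CELL_MAKERS, leakiness_gap_flux, leakiness_line

        maker = _CELL_MAKERS[config.scale_level]
        if config.U is not None:
            U_list = list(config.U)
        else:
            d = maker(config.g_over_d[0]).diameter
            U_list = [
                re * fluid.nominal_kinematic_viscosity / d for re in config.nominal_re
            ]
        rows = []
        for g in sorted(set(config.g_over_d)):
            cell = maker(g)
            for U in sorted(set(U_list)):
                row = {
                    "scale_level": config.scale_level,
                    "g_over_d": g,
                    "U": U,
                    "re_nominal": U * cell.diameter / fluid.nominal_kinematic_viscosity,
                    "le_gap_flux": np.nan,
                    "le_line": np.nan,
                    "converged": False,
                    "residual": np.nan,
                    "error": "",
                }
                try:
                    fld = solve_steady(cell, cell.obstacles(), U, fluid, settings)
                    if "gap_flux" in config.metrics:
                        row["le_gap_flux"] = leakiness_gap_flux(fld).le
                    if "line_average" in config.metrics:
                        row["le_line"] = leakiness_line(fld).le
                    row["converged"] = bool(fld.convergence.get("converged", False))
                    row["residual"] = fld.convergence.get("residual", np.nan)
                    stem = f"field_gd{g:g}_U{U:g}"
                    write_field(fld, out / f"{stem}.h5", seed=config.seed, config_hash=chash)
                    write_field_vtk(fld, out / f"{stem}.vtk")
                except Exception as exc:
                    log.warning("run point G/D=%s U=%s failed: %s", g, U, exc)
                    row["error"] = str(exc)
                rows.append(row)
        table = pd.DataFrame(rows)
        write_table(
            table,
            out / "leakiness.csv",
            units={"U": "cm/s", "le_*": "dimensionless"},
            seed=config.seed,
            config_hash=chash,
        )
        _plot_sweep(table, out)
        if config.capture:
            params = AgentParams(**config.agents)
            re_values = config.nominal_re
            if re_values is None:
                d = maker(config.g_over_d[0]).diameter
                re_values = [u * d / fluid.nominal_kinematic_viscosity for u in config.U]
            results = run_capture_experiment(
                config.g_over_d,
                re_values,
                params=params,
                fluid=fluid,
                settings=settings,
                seed=config.seed,
            )
            write_table(
                capture_table(results),
                out / "capture.csv",
                units={"U": "cm/s", "capture_fraction": "dimensionless"},
                seed=config.seed,
                config_hash=chash,
            )
        log.info("run %s finished", chash)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _plot_sweep(table: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = table[table["error"] == ""]
    if len(ok) == 0:
        return
    for metric, fname in (("le_gap_flux", "le_vs_re.png"), ("le_line", "le_line_vs_re.png")):
        if metric not in ok or ok[metric].isna().all():
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        for g, sub in ok.groupby("g_over_d"):
            ax.plot(sub["re_nominal"], sub[metric], "o-", label=f"G/D={g:g}")
        ax.set_xscale("log")
        ax.set_xlabel("nominal Re")
        ax.set_ylabel(f"leakiness ({metric})")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / fname, dpi=120)
        plt.close(fig)
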