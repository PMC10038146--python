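"""Reynolds/Peclet calculators, porosity coefficient, morphometric ratios.

Two Reynolds conventions coexist: the *true* convention ``Re = rho L U / mu``
with the actual seawater viscosity, and the *nominal* convention
``Re = L U / nu_nominal`` with the rounded kinematic viscosity 0.01 cm^2 s^-1
that labels the integer Reynolds numbers of the simulation campaigns
(Re=2 at U=0.2 cm/s for a 0.1 cm branch, Re=128 at 12.8 cm/s, and the
Pe=32-at-Re=8 pairing all follow this rounding).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .geometry import FluidProperties, SEAWATER

__all__ = [
    "DIFFUSIVITIES",
    "DimensionlessReport",
    "PorosityEstimate",
    "reynolds",
    "speed_for_nominal_reynolds",
    "peclet",
    "porosity_coefficient",
    "morphometric_summary",
    "dimensionless_report",
    "level_report_table",
]

#: Default diffusivities (cm^2 s^-1): plankton active motion treated as an
#: effective diffusivity, plus molecular O2 and CO2.
DIFFUSIVITIES: dict[str, float] = {
    "plankton": 2.5e-3,
    "O2": 1.97e-5,
    "CO2": 1.60e-5,
}


def reynolds(
    fluid: FluidProperties = SEAWATER,
    L: float = 0.1,
    U: float = 1.0,
    convention: Literal["true_viscosity", "nominal"] = "true_viscosity",
) -> float:
    """Reynolds number ``rho L U / mu`` (or ``L U / nu_nominal``)."""
    if L <= 0:
        raise ValueError("characteristic length must be positive")
    if U < 0:
        raise ValueError("speed must be non-negative")
    if convention == "nominal":
        return L * U / fluid.nominal_kinematic_viscosity
    return fluid.density * L * U / fluid.dynamic_viscosity


def speed_for_nominal_reynolds(
    re: float, L: float, fluid: FluidProperties = SEAWATER
) -> float:
    """Inlet speed (cm s^-1) that a nominal Reynolds label corresponds to."""
    return re * fluid.nominal_kinematic_viscosity / L


def peclet(L: float, U: float, d: float) -> float:
    """Peclet number ``L U / d`` — advective over diffusive transport."""
    if d <= 0:
        raise ValueError("diffusivity must be positive")
    return L * U / d


@dataclass(frozen=True)
class PorosityEstimate:
    """Porous-sheet proportionality constant ``Lambda = Le F / U``."""

    porosity: float
    le: float
    force_per_area: float
    U: float


def porosity_coefficient(le: float, force_per_area: float, U: float) -> PorosityEstimate:
    """Approximate the porous-sheet coefficient from leakiness and the steady
    force per unit area at 90 degrees incidence."""
    if U <= 0:
        raise ValueError("free-stream speed must be positive")
    return PorosityEstimate(
        porosity=le * force_per_area / U, le=le, force_per_area=force_per_area, U=U
    )


@dataclass(frozen=True)
class DimensionlessReport:
    """Re and per-substance Pe for one structural level."""

    level: str
    characteristic_length: float
    characteristic_speed: float
    re: float
    re_convention: str
    pe: Mapping[str, float]
    diffusivities: Mapping[str, float]
    fluid: FluidProperties = SEAWATER


def dimensionless_report(
    level: str,
    L: float,
    U: float,
    fluid: FluidProperties = SEAWATER,
    diffusivities: Mapping[str, float] | None = None,
    convention: Literal["true_viscosity", "nominal"] = "nominal",
) -> DimensionlessReport:
    """Assemble Re plus Pe for every substance at one structural level."""
    diffs = dict(DIFFUSIVITIES if diffusivities is None else diffusivities)
    return DimensionlessReport(
        level=level,
        characteristic_length=L,
        characteristic_speed=U,
        re=reynolds(fluid, L, U, convention),
        re_convention=convention,
        pe={name: peclet(L, U, d) for name, d in diffs.items()},
        diffusivities=diffs,
    )


def level_report_table(
    levels: Mapping[str, tuple[float, float]] | Iterable[tuple[str, float, float]],
    fluid: FluidProperties = SEAWATER,
    diffusivities: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Tabulate Re (both conventions) and Pe across structural levels.

    ``levels`` maps level name to (characteristic length cm, speed cm s^-1);
    the characteristic scales are inputs because they vary by colony and
    flow environment.
    """
    if isinstance(levels, Mapping):
        items = [(k, L, U) for k, (L, U) in levels.items()]
    else:
        items = list(levels)
    diffs = dict(DIFFUSIVITIES if diffusivities is None else diffusivities)
    rows = []
    for name, L, U in items:
        row = {
            "level": name,
            "L_cm": L,
            "U_cm_s": U,
            "re_nominal": reynolds(fluid, L, U, "nominal"),
            "re_true": reynolds(fluid, L, U, "true_viscosity"),
        }
        for sub, d in diffs.items():
            row[f"pe_{sub}"] = peclet(L, U, d)
        rows.append(row)
    return pd.DataFrame(rows)


def morphometric_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen gap/diameter and height/diameter ratio statistics.

    ``records`` needs columns ``specimen``, ``gap``, ``diameter`` and
    optionally ``height`` and ``unit``; lengths may be calibrated (cm) or
    uncalibrated (pixels), but ratios are only formed within a specimen, so
    mixed units across specimens are fine while mixed units *within* one
    specimen raise.
    """
    df = pd.DataFrame(records)
    required = {"specimen", "gap", "diameter"}
    if not required.issubset(df.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError("need at least one record")
    if (df[["gap", "diameter"]] <= 0).any().any():
        raise ValueError("lengths must be positive")
    if "unit" in df.columns:
        per_unit = df.groupby("specimen")["unit"].nunique()
        if (per_unit > 1).any():
            raise ValueError("mixed units within a specimen; calibrate first")
    df = df.copy()
    df["g_over_d"] = df["gap"] / df["diameter"]
    if "height" in df.columns:
        df["h_over_d"] = df["height"] / df["diameter"]
    agg = {"g_over_d": ["mean", "std", "count"]}
    if "h_over_d" in df.columns:
        agg["h_over_d"] = ["mean", "std"]
    out = df.groupby("specimen").agg(agg)
    out.columns = ["_".join(c) for c in out.columns]
    out = out.rename(columns={"g_over_d_count": "n_measurements"})
    # a single measurement has no dispersion, not an undefined one
    for col in out.columns:
        if col.endswith("_std"):
            out[col] = out[col].fillna(0.0)
    if "unit" in df.columns:
        out["unit"] = df.groupby("specimen")["unit"].first()
    return out.reset_index()
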