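"""Shared fixtures: a session-scoped cache of steady solves.

Flow solves dominate the suite's runtime, and many tests interrogate the
same handful of fields, so solves are cached per (scale, G/D, U, preset,
decorated) for the whole session.  Presets bundle the solver settings used
for different jobs: ``default`` for quantitative leakiness measurements,
``highre`` tolerates the residual limit cycle of the fastest flows,
``capture``/``loose`` trade residual depth for speed where only large-scale
flow structure matters, ``fine`` is the refined grid for convergence checks
and ``polyp`` resolves the decorated cylinder.
"""

from __future__ import annotations

import warnings

import pytest

import coralflow as cf
from coralflow.solver import SolverSettings

PRESETS: dict[str, dict] = {
    "default": {},
    "highre": {"plateau_factor": 100.0},
    "capture": {"tolerance": 3e-3, "plateau_factor": 30.0},
    "loose": {"plateau_factor": 30.0},
    "fine": {"n_per_diameter": 10},
    "polyp": {"axial_coarsen": 1.5, "mask_inflate": 0.6},
}

_MAKERS = {
    "branch": cf.make_branch_cell,
    "tentacle": cf.make_tentacle_cell,
    "pinnule": cf.make_pinnule_cell,
}


@pytest.fixture(scope="session")
def solve_cached():
    """Callable returning (and caching) steady cell solutions."""
    cache: dict = {}

    def get(scale: str, g: float, U: float, preset: str = "default",
            polyps: bool = False) -> cf.FlowField:
        key = (scale, g, U, preset, polyps)
        if key not in cache:
            cell = _MAKERS[scale](g)
            obs = cf.make_polyp_cylinder(cell) if polyps else cell.obstacles()
            settings = SolverSettings(**PRESETS[preset])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cache[key] = cf.solve_steady(cell, obs, U, settings=settings)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def capture_fields():
    """Field cache shared by the capture-experiment tests."""
    return {}


@pytest.fixture(scope="session")
def branch_cell():
    return cf.make_branch_cell(2.0)
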