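"""Shared fixtures: internally optimized geometries and cached solvated runs.

Everything is generated at test time; the session scope keeps the expensive
self-consistent runs (geometry optimization, PCM-VQE) to one evaluation each.
"""
from __future__ import annotations

import numpy as np
import pytest

from pcmvqe import (RunConfig, SolventParams, build_problem, optimize_geometry,
                    run_solvation)
from pcmvqe.driver import Problem


@pytest.fixture(scope="session")
def h3p_geometry():
    return optimize_geometry("h3+")


@pytest.fixture(scope="session")
def beh2_geometry():
    return optimize_geometry("beh2")


@pytest.fixture(scope="session")
def h2o_geometry():
    return optimize_geometry("h2o")


@pytest.fixture(scope="session")
def h2o_equilibrium(h2o_geometry):
    """(r_OH angstrom, HOH angle degrees) of the optimized water geometry."""
    v1 = h2o_geometry.coords[1] - h2o_geometry.coords[0]
    v2 = h2o_geometry.coords[2] - h2o_geometry.coords[0]
    r = float(np.linalg.norm(v1))
    ang = float(np.degrees(np.arccos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))))
    return r, ang


@pytest.fixture(scope="session")
def h3p_problem_dmso(h3p_geometry) -> Problem:
    return build_problem(RunConfig(geometry=h3p_geometry, solvent=SolventParams()))


@pytest.fixture(scope="session")
def h3p_solvation(h3p_geometry):
    return run_solvation(RunConfig(geometry=h3p_geometry, solvent=SolventParams()))


@pytest.fixture(scope="session")
def beh2_solvation(beh2_geometry):
    return run_solvation(
        RunConfig(geometry=beh2_geometry, frozen_orbitals=1, solvent=SolventParams()))


@pytest.fixture(scope="session")
def h2o_solvation(h2o_geometry):
    return run_solvation(
        RunConfig(geometry=h2o_geometry, frozen_orbitals=1, solvent=SolventParams()))
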