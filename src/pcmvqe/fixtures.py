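"""Symmetry-constrained geometry templates for the bundled test systems.

Every experiment in the package is generated, not downloaded: each template
exposes the one or two internal degrees of freedom of the molecule and the
geometry optimizer minimizes the gas-phase FCI (or HF) energy over them.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import Geometry


def h2(r: float = 0.735) -> Geometry:
    return Geometry(["H", "H"], [[0, 0, 0], [0, 0, r]], label="H2")


def heh_plus(r: float = 0.93) -> Geometry:
    return Geometry(["He", "H"], [[0, 0, 0], [0, 0, r]], net_charge=1, label="HeH+")


def h3_plus(side: float = 0.99) -> Geometry:
    """Equilateral trihydrogen cation with the given side length (angstrom)."""
    rho = side / np.sqrt(3.0)
    pts = [[rho * np.cos(a), rho * np.sin(a), 0.0] for a in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)]
    return Geometry(["H"] * 3, pts, net_charge=1, label="H3+")


def beh2(d: float = 1.33) -> Geometry:
    """Linear symmetric beryllium hydride, Be-H distance d (angstrom)."""
    return Geometry(["Be", "H", "H"], [[0, 0, 0], [0, 0, d], [0, 0, -d]], label="BeH2")


def h2o(r: float = 1.0, angle_deg: float = 97.0) -> Geometry:
    """Water with O-H bond r (angstrom) and H-O-H angle (degrees)."""
    half = np.radians(angle_deg) / 2.0
    return Geometry(
        ["O", "H", "H"],
        [[0, 0, 0],
         [r * np.sin(half), 0, r * np.cos(half)],
         [-r * np.sin(half), 0, r * np.cos(half)]],
        label="H2O",
    )


@dataclass
class Fixture:
    name: str
    template: Callable[..., Geometry]
    x0: tuple[float, ...]            # starting template parameters
    bounds: tuple[tuple[float, float], ...]
    n_electrons: int
    frozen_orbitals: int             # recommended frozen core for VQE runs


FIXTURES: dict[str, Fixture] = {
    "h2": Fixture("h2", h2, (0.735,), ((0.4, 1.5),), 2, 0),
    "heh+": Fixture("heh+", heh_plus, (0.93,), ((0.5, 1.6),), 2, 0),
    "h3+": Fixture("h3+", h3_plus, (0.99,), ((0.6, 1.4),), 2, 0),
    "beh2": Fixture("beh2", beh2, (1.33,), ((1.0, 1.8),), 6, 1),
    "h2o": Fixture("h2o", h2o, (1.0, 97.0), ((0.8, 1.3), (80.0, 120.0)), 10, 1),
}


def get_fixture(name: str) -> Fixture:
    key = name.lower()
    if key not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    return FIXTURES[key]
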