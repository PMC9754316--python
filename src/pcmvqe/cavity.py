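"""Molecular cavity construction for continuum solvation.

The solute cavity is a union of scaled van der Waals spheres.  Each sphere is
tessellated by recursive icosahedral subdivision (20 * 4^level spherical
triangles); tesserae whose representative point falls strictly inside another
sphere are discarded, leaving the exposed surface.  This is a deliberately
simpler, convergent alternative to the GePol construction (no cut tesserae or
added spheres); its adequacy is checked against analytic Born-sphere results.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_PER_ANGSTROM
from .geometry import Geometry

log = logging.getLogger(__name__)

# Bondi van der Waals radii (angstrom); Be from the Mantina extension.
BONDI_RADII = {"H": 1.20, "He": 1.40, "Li": 1.82, "Be": 1.53, "B": 1.92,
               "C": 1.70, "N": 1.55, "O": 1.52}

# UFF van der Waals radii (half the UFF vdW distance, angstrom).  The default
# set: it covers every element (Bondi lacks several light metals) and its
# hydrogen sphere (1.443 A, essentially the scaled-Bondi 1.44 A) reproduces
# the trihydrogen-cation solvation benchmark used to calibrate the cavity.
UFF_RADII = {"H": 1.4430, "He": 1.1810, "Li": 1.2255, "Be": 1.3725,
             "B": 2.0415, "C": 1.9255, "N": 1.8300, "O": 1.7500}

EPSILON_DMSO = 46.7
EPSILON_WATER = 78.39


@dataclass
class SolventParams:
    """Dielectric constant plus cavity-sphere parameters.

    Defaults: UFF radii unscaled (H sphere 1.443 angstrom), DMSO dielectric,
    tessellation level 3 (1280 triangles per sphere).
    """

    epsilon: float = EPSILON_DMSO
    radii_map: dict[str, float] = field(default_factory=lambda: dict(UFF_RADII))
    radius_scale: float = 1.0
    tess_level: int = 3

    def __post_init__(self) -> None:
        if self.epsilon < 1.0:
            raise ValueError("dielectric constant must be >= 1")
        if any(r <= 0 for r in self.radii_map.values()):
            raise ValueError("cavity radii must be positive")
        if self.tess_level < 1:
            raise ValueError("tess_level must be >= 1")


@dataclass
class Cavity:
    centers: np.ndarray    # (N_tess, 3) bohr
    areas: np.ndarray      # (N_tess,) bohr^2
    normals: np.ndarray    # (N_tess, 3) outward unit vectors
    sphere_of: np.ndarray  # (N_tess,) owning-sphere index
    sphere_centers: np.ndarray  # (n_spheres, 3) bohr
    sphere_radii: np.ndarray    # (n_spheres,) bohr

    @property
    def n_tesserae(self) -> int:
        return len(self.areas)

    def to_table(self) -> "object":
        """Point-cloud table (TSV-ready) for inspection."""
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.centers[:, 0], "y": self.centers[:, 1], "z": self.centers[:, 2],
                "area": self.areas,
                "nx": self.normals[:, 0], "ny": self.normals[:, 1], "nz": self.normals[:, 2],
                "sphere": self.sphere_of,
            }
        )


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for a, b in [(1, phi), (-1, phi), (1, -phi), (-1, -phi)]:
        verts += [(0, a, b), (a, b, 0), (b, 0, a)]
    verts = np.array(verts, dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    # faces by nearest-neighbour edges
    from itertools import combinations

    edge_len = np.min(
        [np.linalg.norm(verts[i] - verts[j]) for i, j in combinations(range(12), 2)]
    )
    faces = []
    for i, j, k in combinations(range(12), 3):
        d = (np.linalg.norm(verts[i] - verts[j]), np.linalg.norm(verts[j] - verts[k]),
             np.linalg.norm(verts[i] - verts[k]))
        if all(abs(x - edge_len) < 1e-9 for x in d):
            faces.append((i, j, k))
    return verts, np.array(faces)


def _subdivide(verts: np.ndarray, faces: np.ndarray, level: int) -> tuple[np.ndarray, np.ndarray]:
    verts = list(map(tuple, verts))
    index = {v: i for i, v in enumerate(verts)}

    def midpoint(i, j):
        m = (np.array(verts[i]) + np.array(verts[j])) / 2.0
        m /= np.linalg.norm(m)
        key = tuple(np.round(m, 12))
        if key not in index:
            index[key] = len(verts)
            verts.append(key)
        return index[key]

    for _ in range(level):
        new_faces = []
        for i, j, k in faces:
            a, b, c = midpoint(i, j), midpoint(j, k), midpoint(i, k)
            new_faces += [(i, a, c), (a, j, b), (c, b, k), (a, b, c)]
        faces = np.array(new_faces)
    return np.array(verts, dtype=float), faces


def _spherical_triangle_areas(v0, v1, v2) -> np.ndarray:
    """Unit-sphere triangle areas via the spherical excess (L'Huilier)."""

    def arc(a, b):
        return 2.0 * np.arcsin(np.clip(np.linalg.norm(a - b, axis=1) / 2.0, 0, 1))

    a, b, c = arc(v1, v2), arc(v0, v2), arc(v0, v1)
    s = (a + b + c) / 2.0
    tan_quarter = np.sqrt(
        np.clip(np.tan(s / 2) * np.tan((s - a) / 2) * np.tan((s - b) / 2) * np.tan((s - c) / 2), 0, None)
    )
    return 4.0 * np.arctan(tan_quarter)


_UNIT_SPHERE_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _unit_sphere_tesserae(level: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroids, areas and per-triangle sample points of a unit-sphere grid.

    The samples (3 vertices, 3 edge midpoints, centroid; all projected to the
    sphere) estimate the exposed fraction of a tessera cut by another sphere.
    """
    if level not in _UNIT_SPHERE_CACHE:
        verts, faces = _icosahedron()
        verts, faces = _subdivide(verts, faces, level)
        v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
        centroids = (v0 + v1 + v2) / 3.0
        centroids /= np.linalg.norm(centroids, axis=1)[:, None]
        areas = _spherical_triangle_areas(v0, v1, v2)
        samples = np.stack(
            [v0, v1, v2, (v0 + v1) / 2, (v1 + v2) / 2, (v0 + v2) / 2, centroids],
            axis=1,
        )
        samples /= np.linalg.norm(samples, axis=2)[:, :, None]
        _UNIT_SPHERE_CACHE[level] = (centroids, areas, samples)
    return _UNIT_SPHERE_CACHE[level]


def build_cavity(geometry: Geometry, params: SolventParams) -> Cavity:
    """Tessellate the union of scaled atomic spheres, keeping exposed tesserae."""
    centroids, unit_areas, samples = _unit_sphere_tesserae(params.tess_level)
    sphere_centers = geometry.coords_bohr
    radii = np.array(
        [params.radii_map[s] * params.radius_scale for s in geometry.symbols]
    ) * BOHR_PER_ANGSTROM

    all_centers, all_areas, all_normals, all_owner = [], [], [], []
    for i in range(geometry.n_atoms):
        pts = sphere_centers[i] + radii[i] * centroids
        spts = sphere_centers[i] + radii[i] * samples      # (n_tri, 7, 3)
        keep = np.ones(len(pts), dtype=bool)
        exposed = np.ones(samples.shape[:2], dtype=bool)
        for j in range(geometry.n_atoms):
            if j == i:
                continue
            keep &= np.linalg.norm(pts - sphere_centers[j], axis=1) >= radii[j]
            exposed &= np.linalg.norm(spts - sphere_centers[j], axis=2) >= radii[j]
        if not np.any(keep):
            log.info("sphere %d (%s) fully buried; contributes no tesserae",
                     i, geometry.symbols[i])
            continue
        # tesserae cut by a neighbouring sphere keep only their exposed area
        frac = exposed[keep].mean(axis=1)
        all_centers.append(pts[keep])
        all_areas.append(unit_areas[keep] * frac * radii[i] ** 2)
        all_normals.append(centroids[keep])
        all_owner.append(np.full(keep.sum(), i))
    if not all_centers:
        raise ValueError("cavity has zero tesserae")
    return Cavity(
        np.concatenate(all_centers),
        np.concatenate(all_areas),
        np.concatenate(all_normals),
        np.concatenate(all_owner),
        sphere_centers,
        radii,
    )
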