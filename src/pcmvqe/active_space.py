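"""Transformation of AO integrals to an active molecular-orbital space.

Frozen (core) orbitals contribute their mean field to the one-body active
integrals and their energy to the scalar offset.  For a solvated calculation
the frozen-core electron density's electrostatic potential at the tessera
points is folded into the *static* potential alongside the nuclei, so the
static apparent surface charges represent nuclei + frozen core.  This keeps
the active-space free energy exact in the vacuum limit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry, nuclear_potential
from .integrals import CoreIntegrals
from .scf import ScfResult


@dataclass
class ActiveSpaceIntegrals:
    """MO-basis integrals over the active orbitals (chemists' ERI ordering)."""

    h: np.ndarray          # (n_act, n_act) one-body, Hartree
    g: np.ndarray          # (n_act,)*4 two-body (pq|rs), Hartree
    e_offset: float        # nuclear repulsion + frozen-core energy, Hartree
    n_active_electrons: int
    K: np.ndarray | None = None         # (n_act, n_act, N_tess) tessera potentials
    v_static: np.ndarray | None = None  # (N_tess,) nuclei + frozen core potential

    @property
    def n_act(self) -> int:
        return self.h.shape[0]


def active_space_transform(
    core: CoreIntegrals,
    scf: ScfResult,
    n_electrons: int,
    frozen_orbitals: int = 0,
    active_orbitals: int | None = None,
    K_ao: np.ndarray | None = None,
    geometry: Geometry | None = None,
    tessera_points: np.ndarray | None = None,
) -> ActiveSpaceIntegrals:
    """Fold frozen-core mean field into active-space (h, g, K, v_static).

    ``frozen_orbitals`` lowest-energy occupied MOs are frozen; the active
    window is the next ``active_orbitals`` MOs (default: all remaining).
    """
    C = scf.mo_coefficients
    n_mo = C.shape[1]
    if active_orbitals is None:
        active_orbitals = n_mo - frozen_orbitals
    if frozen_orbitals + active_orbitals > n_mo:
        raise ValueError("frozen + active orbitals exceed the MO space")
    if 2 * frozen_orbitals > n_electrons:
        raise ValueError("more frozen orbitals than electron pairs")
    C_frozen = C[:, :frozen_orbitals]
    C_act = C[:, frozen_orbitals : frozen_orbitals + active_orbitals]

    h_ao = core.kinetic + core.nuclear_attraction
    e_offset = core.e_nn
    if frozen_orbitals:
        D_fc = 2.0 * C_frozen @ C_frozen.T
        J = np.einsum("pqrs,rs->pq", core.eri, D_fc)
        Kx = np.einsum("prqs,rs->pq", core.eri, D_fc)
        v_fc = J - 0.5 * Kx
        e_offset += np.einsum("pq,pq->", D_fc, h_ao + 0.5 * v_fc)
        h_ao = h_ao + v_fc
    else:
        D_fc = None

    h = C_act.T @ h_ao @ C_act
    g = np.einsum("pqrs,pi,qj,rk,sl->ijkl", core.eri, C_act, C_act, C_act, C_act,
                  optimize=True)

    K = v_static = None
    if K_ao is not None:
        K = np.einsum("pqi,pj,qk->jki", K_ao, C_act, C_act, optimize=True)
        if geometry is None or tessera_points is None:
            raise ValueError("geometry and tessera_points required with K_ao")
        v_static = nuclear_potential(geometry, tessera_points)
        if D_fc is not None:
            v_static = v_static + np.einsum("pq,pqi->i", D_fc, K_ao)

    return ActiveSpaceIntegrals(
        h=h, g=g, e_offset=float(e_offset),
        n_active_electrons=n_electrons - 2 * frozen_orbitals,
        K=K, v_static=v_static,
    )
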