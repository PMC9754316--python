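"""Restricted Hartree-Fock, gas phase or coupled to an IEF-PCM reaction field.

A DIIS-free damped Roothaan iteration is sufficient at minimal-basis sizes.
With a PCM environment the Fock operator gains the one-body solvent term built
from the apparent surface charges of the current density, and the reported
figure is the free energy in solution G = E[rho] + 1/2 V^T Q V.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals import CoreIntegrals


class ScfConvergenceError(RuntimeError):
    def __init__(self, msg: str, last_energy: float):
        super().__init__(f"{msg} (last energy {last_energy:.10f} Ha)")
        self.last_energy = last_energy


@dataclass
class PcmEnvironment:
    """Everything the SCF needs to couple to the polarizable continuum."""

    Q: np.ndarray          # solvent response matrix (N_tess x N_tess)
    K_ao: np.ndarray       # AO tessera-potential tensor (n_ao, n_ao, N_tess)
    v_static: np.ndarray   # nuclear potential at tesserae (N_tess,)


@dataclass
class ScfResult:
    mo_coefficients: np.ndarray
    orbital_energies: np.ndarray
    e_total: float          # E (gas) or free energy G (PCM run)
    density: np.ndarray     # spin-summed AO density, trace(D S) = n_electrons
    converged: bool
    n_iterations: int


def _fock(h: np.ndarray, eri: np.ndarray, D: np.ndarray) -> np.ndarray:
    J = np.einsum("pqrs,rs->pq", eri, D)
    K = np.einsum("prqs,rs->pq", eri, D)
    return h + J - 0.5 * K


def run_hf(
    core: CoreIntegrals,
    n_electrons: int,
    pcm: PcmEnvironment | None = None,
    max_cycles: int = 800,
    conv_energy: float = 1e-10,
    conv_commutator: float = 1e-8,
    damping: float = 0.35,
    level_shift: float = 0.0,
    _retry: bool = True,
) -> ScfResult:
    """Converge a closed-shell RHF (optionally PCM-coupled) wavefunction.

    If the damped Roothaan iteration oscillates (typical for stretched
    bonds), the solver retries with heavier damping and a virtual-orbital
    level shift before giving up.
    """
    if n_electrons % 2 != 0:
        raise ValueError("restricted closed-shell HF needs an even electron count")
    n_occ = n_electrons // 2
    S, h = core.overlap, core.kinetic + core.nuclear_attraction
    s_val, s_vec = np.linalg.eigh(S)
    if s_val.min() < 1e-8:
        raise ValueError("overlap matrix nearly singular")
    X = s_vec @ np.diag(s_val**-0.5) @ s_vec.T

    def solvent_term(D):
        V = pcm.v_static + np.einsum("pq,pqi->i", D, pcm.K_ao)
        q = pcm.Q @ V
        return V, q, np.einsum("pqi,i->pq", pcm.K_ao, q)

    def total_energy(D, F_gas):
        e = 0.5 * np.einsum("pq,pq->", D, h + F_gas) + core.e_nn
        if pcm is not None:
            V, q, _ = solvent_term(D)
            e += 0.5 * float(V @ q)
        return e

    # core-Hamiltonian guess
    F = h.copy()
    D = np.zeros_like(S)
    P_prev = None  # occupied projector in the orthonormal basis
    energy = 0.0
    converged = False
    for cycle in range(1, max_cycles + 1):
        Fp = X.T @ F @ X
        if level_shift > 0.0 and P_prev is not None:
            Fp = Fp + level_shift * (np.eye(len(S)) - P_prev)
        eps, Cp = np.linalg.eigh(Fp)
        C = X @ Cp
        P_prev = Cp[:, :n_occ] @ Cp[:, :n_occ].T
        D_new = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        if cycle > 1:
            D_new = (1.0 - damping) * D_new + damping * D
        D = D_new
        F_gas = _fock(h, core.eri, D)
        F = F_gas if pcm is None else F_gas + solvent_term(D)[2]
        new_energy = total_energy(D, F_gas)
        commutator = X.T @ (F @ D @ S - S @ D @ F) @ X
        if abs(new_energy - energy) < conv_energy and np.abs(commutator).max() < conv_commutator:
            energy = new_energy
            converged = True
            break
        energy = new_energy
    if not converged:
        if _retry:
            for damp, shift in ((0.5, 0.0), (0.65, 0.3), (0.8, 1.0)):
                try:
                    return run_hf(core, n_electrons, pcm, max_cycles * 2, conv_energy,
                                  conv_commutator, damp, shift, _retry=False)
                except ScfConvergenceError:
                    continue
        raise ScfConvergenceError(f"SCF not converged in {max_cycles} cycles", energy)

    # final diagonalization for self-consistent orbitals
    Fp = X.T @ F @ X
    eps, Cp = np.linalg.eigh(Fp)
    C = X @ Cp
    D = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
    energy = total_energy(D, _fock(h, core.eri, D))
    return ScfResult(C, eps, energy, D, True, cycle)
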