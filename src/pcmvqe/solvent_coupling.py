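"""Second-quantized solute-solvent coupling and the free-energy functional.

The solvated objective evaluated from measured reduced density matrices is

    G(gamma, Gamma) = E_offset + sum_pq h_pq gamma_pq
                      + 1/2 sum_pqrs g_pqrs Gamma_pqrs
                      + 1/2 V_tot^T Q V_tot,

with V_tot = v_static + v_el(gamma) the molecular electrostatic potential at
the tessera points (nuclei + frozen core plus the active electrons).  The
1/2 prefactor on the polarization term is the work spent polarizing the
dielectric; with a symmetric response matrix the nuclear->electron and
electron->nuclear couplings coincide (j = y).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

from .active_space import ActiveSpaceIntegrals
from .constants import EV_PER_HARTREE


@dataclass
class Rdms:
    """Spatial-orbital one- and two-electron reduced density matrices.

    ``gamma[p, q] = <E_pq>`` and ``Gamma[p, q, r, s] = <E_pq E_rs - d_qr E_ps>``
    (chemists' index pairing, matching the (pq|rs) ERI ordering).
    """

    gamma: np.ndarray
    Gamma: np.ndarray

    def validate(self, n_electrons: int, tol: float = 1e-6) -> None:
        tr = float(np.trace(self.gamma))
        if abs(tr - n_electrons) > tol:
            raise ValueError(f"trace(gamma) = {tr:.8f}, expected {n_electrons}")


@dataclass
class SolventCouplings:
    """Static apparent charges and one-body coupling matrices for a cavity."""

    Q: np.ndarray
    K: np.ndarray            # (n_act, n_act, N_tess)
    v_static: np.ndarray
    q_static: np.ndarray = field(init=False)
    W_NN: float = field(init=False)
    j: np.ndarray = field(init=False)
    y: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.q_static, self.W_NN = static_asc(self.v_static, self.Q)
        self.j, self.y = one_body_couplings(self.K, self.q_static, self.v_static, self.Q)


def static_asc(v_static: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, float]:
    """ASC of the static (nuclei + frozen core) potential and W_NN = v^T q."""
    q_static = Q @ v_static
    return q_static, float(v_static @ q_static)


def one_body_couplings(K, q_static, v_static, Q) -> tuple[np.ndarray, np.ndarray]:
    """Coupling matrices j (electrons with static ASC) and y (nuclei with
    electron-generated ASC); equal for a symmetric response matrix."""
    j = np.einsum("pqi,i->pq", K, q_static)
    y = np.einsum("i,ipq->pq", v_static, np.einsum("ij,pqj->ipq", Q, K))
    return j, y


def electronic_asc(gamma: np.ndarray, K: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """ASC induced by the active-electron density."""
    v_el = np.einsum("pq,pqi->i", gamma, K)
    return Q @ v_el


@dataclass
class FreeEnergyReport:
    """Decomposed solvated energy; the provenance record of every run."""

    e_gas: float            # gas-phase expectation <H> (Hartree)
    u_int: float            # full quadratic form V_tot^T Q V_tot (Hartree)
    g_total: float          # free energy in solution G = e_gas + u_int / 2
    w_nn: float             # static-static interaction v_static^T q_static
    e_static_coupling: float   # electron - static-ASC interaction (2 j.gamma)
    e_electron_coupling: float # electron - electron-ASC interaction
    q_total: np.ndarray | None = None
    delta_solv_ev: float | None = None

    def to_json(self, **metadata) -> str:
        payload = asdict(self)
        payload["q_total"] = None if self.q_total is None else list(map(float, self.q_total))
        payload.update(metadata)
        return json.dumps(payload, indent=2, default=float)


def free_energy(
    rdms: Rdms,
    integrals: ActiveSpaceIntegrals,
    couplings: SolventCouplings | None,
    check_trace: bool = True,
) -> FreeEnergyReport:
    """Evaluate the free-energy functional from RDMs.

    With ``couplings=None`` (or epsilon = 1, where Q = 0) this reduces to the
    gas-phase energy expectation.  ``check_trace`` guards against
    mis-normalized (e.g. noisy, unnormalized) RDMs.
    """
    if check_trace:
        rdms.validate(integrals.n_active_electrons)
    e_gas = (
        integrals.e_offset
        + float(np.einsum("pq,pq->", integrals.h, rdms.gamma))
        + 0.5 * float(np.einsum("pqrs,pqrs->", integrals.g, rdms.Gamma))
    )
    if couplings is None:
        return FreeEnergyReport(e_gas, 0.0, e_gas, 0.0, 0.0, 0.0)

    v_el = np.einsum("pq,pqi->i", rdms.gamma, couplings.K)
    v_tot = couplings.v_static + v_el
    q_tot = couplings.Q @ v_tot
    u_int = float(v_tot @ q_tot)
    e_static = 2.0 * float(np.einsum("pq,pq->", couplings.j, rdms.gamma))
    e_electron = float(v_el @ (couplings.Q @ v_el))
    return FreeEnergyReport(
        e_gas=e_gas,
        u_int=u_int,
        g_total=e_gas + 0.5 * u_int,
        w_nn=couplings.W_NN,
        e_static_coupling=e_static,
        e_electron_coupling=e_electron,
        q_total=q_tot,
    )


def polarization_energy(
    gamma_gas: np.ndarray,
    integrals: ActiveSpaceIntegrals,
    couplings: SolventCouplings,
) -> float:
    """U_pol = 1/2 V(gamma_gas)^T Q V(gamma_gas): interaction of the frozen
    gas-phase density with the charges it induces (no wavefunction relaxation)."""
    v_el = np.einsum("pq,pqi->i", gamma_gas, couplings.K)
    v_tot = couplings.v_static + v_el
    return 0.5 * float(v_tot @ (couplings.Q @ v_tot))


def solvation_free_energy(g_solution: float, e_gas: float) -> float:
    """Delta G_solv = (G - E_gas) in eV."""
    return (g_solution - e_gas) * EV_PER_HARTREE
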