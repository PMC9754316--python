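"""Full configuration interaction in a fixed (N_alpha, N_beta) sector.

Determinants are encoded as spin-orbital occupation bitmasks using the same
interleaved convention as the qubit register, so a CI vector embeds directly
into the statevector simulator.  The Hamiltonian is never built densely:
its action is assembled from cached sparse singlet-excitation matrices,
    H v = E_off v + sum_pq h~_pq (E_pq v) + 1/2 sum_pq E_pq (sum_rs g_pqrs E_rs v),
which keeps the cost at ~2 n^2 sparse matvecs per application.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .active_space import ActiveSpaceIntegrals
from .solvent_coupling import Rdms, SolventCouplings


def determinant_basis(n_spatial: int, n_alpha: int, n_beta: int) -> np.ndarray:
    """Sorted occupation bitmasks of the (N_alpha, N_beta) determinant space."""
    alphas = [sum(1 << (2 * p) for p in occ) for occ in combinations(range(n_spatial), n_alpha)]
    betas = [sum(1 << (2 * p + 1) for p in occ) for occ in combinations(range(n_spatial), n_beta)]
    dets = np.array([a | b for a in alphas for b in betas], dtype=np.int64)
    dets.sort()
    return dets


def _a_dag_a_sector(dets: np.ndarray, p: int, q: int) -> sp.csr_matrix:
    """Sparse a^dag_p a_q (spin-orbital indices) in the determinant basis."""
    dim = len(dets)
    if p == q:
        occ = ((dets >> p) & 1).astype(float)
        return sp.diags(occ).tocsr()
    sel = (((dets >> q) & 1) == 1) & (((dets >> p) & 1) == 0)
    rows_src = np.nonzero(sel)[0]
    src = dets[sel]
    sign_q = 1 - 2 * (np.bitwise_count(src & ((1 << q) - 1)).astype(np.int64) & 1)
    mid = src ^ (1 << q)
    sign_p = 1 - 2 * (np.bitwise_count(mid & ((1 << p) - 1)).astype(np.int64) & 1)
    dst = mid ^ (1 << p)
    cols_dst = np.searchsorted(dets, dst)
    return sp.csr_matrix(
        ((sign_q * sign_p).astype(float), (cols_dst, rows_src)), shape=(dim, dim)
    )


class SectorOperators:
    """Cached sector matrices of the singlet excitations E_pq."""

    def __init__(self, n_spatial: int, n_alpha: int, n_beta: int):
        self.n_spatial = n_spatial
        self.dets = determinant_basis(n_spatial, n_alpha, n_beta)
        self.dim = len(self.dets)
        self.e_pq = [
            [
                (_a_dag_a_sector(self.dets, 2 * p, 2 * q)
                 + _a_dag_a_sector(self.dets, 2 * p + 1, 2 * q + 1)).tocsr()
                for q in range(n_spatial)
            ]
            for p in range(n_spatial)
        ]

    def excitation_stack(self, v: np.ndarray) -> np.ndarray:
        n = self.n_spatial
        W = np.empty((n, n, self.dim))
        for p in range(n):
            for q in range(n):
                W[p, q] = self.e_pq[p][q] @ v
        return W

    def gamma(self, v: np.ndarray) -> np.ndarray:
        n = self.n_spatial
        return np.array([[v @ (self.e_pq[p][q] @ v) for q in range(n)] for p in range(n)])

    def rdms(self, v: np.ndarray) -> Rdms:
        W = self.excitation_stack(v)
        gamma = np.einsum("d,pqd->pq", v, W)
        Gamma = np.einsum("qpd,rsd->pqrs", W, W)
        Gamma -= np.einsum("qr,ps->pqrs", np.eye(self.n_spatial), gamma)
        return Rdms(gamma, Gamma)

    def hamiltonian_action(self, h: np.ndarray, g: np.ndarray, e_offset: float):
        n = self.n_spatial
        h_eff = h - 0.5 * np.einsum("prrq->pq", g)

        def matvec(v: np.ndarray) -> np.ndarray:
            v = np.asarray(v).ravel()
            W = self.excitation_stack(v)
            out = e_offset * v + np.einsum("pq,pqd->d", h_eff, W)
            B = np.einsum("pqrs,rsd->pqd", g, W, optimize=True)
            for p in range(n):
                for q in range(n):
                    out += 0.5 * (self.e_pq[p][q] @ B[p, q])
            return out

        return matvec

    def ground_state(self, h: np.ndarray, g: np.ndarray, e_offset: float,
                     v0: np.ndarray | None = None) -> tuple[float, np.ndarray]:
        matvec = self.hamiltonian_action(h, g, e_offset)
        if self.dim <= 64:
            H = np.column_stack([matvec(col) for col in np.eye(self.dim)])
            w, vecs = np.linalg.eigh(0.5 * (H + H.T))
            return float(w[0]), vecs[:, 0]
        op = spla.LinearOperator((self.dim, self.dim), matvec=matvec, dtype=float)
        w, vecs = spla.eigsh(op, k=1, which="SA", v0=v0, maxiter=5000, tol=1e-12)
        v = vecs[:, 0]
        return float(w[0]), v / np.linalg.norm(v)

    def embed(self, v: np.ndarray, n_qubits: int) -> np.ndarray:
        """Lift a sector CI vector into the full 2^N statevector."""
        state = np.zeros(2**n_qubits, dtype=complex)
        state[self.dets] = v
        return state

    def extract(self, state: np.ndarray) -> np.ndarray:
        return np.real(state[self.dets]).copy()


def _sector(integrals: ActiveSpaceIntegrals, n_electrons: int, sz2: int = 0) -> SectorOperators:
    n_alpha = (n_electrons + sz2) // 2
    n_beta = n_electrons - n_alpha
    return SectorOperators(integrals.n_act, n_alpha, n_beta)


def run_fci(
    integrals: ActiveSpaceIntegrals,
    n_electrons: int | None = None,
    pcm: str | None = None,
    couplings: SolventCouplings | None = None,
    max_outer: int = 100,
    conv: float = 1e-10,
) -> tuple[float, np.ndarray, SectorOperators]:
    """FCI ground state: gas phase, rigid PCM, or self-consistent PCM.

    ``pcm=None`` returns the gas-phase energy; ``"rigid"`` adds the
    polarization energy of the frozen gas-phase density (no relaxation);
    ``"self_consistent"`` iterates diagonalization of the effective
    Hamiltonian and reports the converged free energy G.
    Returns (energy_or_G, ci_vector, sector).
    """
    if n_electrons is None:
        n_electrons = integrals.n_active_electrons
    sec = _sector(integrals, n_electrons)
    if sec.dim > 10**6:
        raise ValueError(f"determinant space too large ({sec.dim})")
    e_gas, v = sec.ground_state(integrals.h, integrals.g, integrals.e_offset)
    if pcm is None:
        return e_gas, v, sec
    if couplings is None:
        raise ValueError("PCM modes need solvent couplings")

    def polarization(gamma):
        v_tot = couplings.v_static + np.einsum("pq,pqi->i", gamma, couplings.K)
        return 0.5 * float(v_tot @ (couplings.Q @ v_tot)), v_tot

    if pcm == "rigid":
        u_pol, _ = polarization(sec.gamma(v))
        return e_gas + u_pol, v, sec
    if pcm != "self_consistent":
        raise ValueError(f"unknown pcm mode {pcm!r}")

    G = e_gas
    for _ in range(max_outer):
        gamma = sec.gamma(v)
        _, v_tot = polarization(gamma)
        q_tot = couplings.Q @ v_tot
        h_eff = integrals.h + np.einsum("pqi,i->pq", couplings.K, q_tot)
        _, v = sec.ground_state(h_eff, integrals.g, integrals.e_offset, v0=v)
        gamma = sec.gamma(v)
        rd = sec.rdms(v)
        e_exp = (
            integrals.e_offset
            + float(np.einsum("pq,pq->", integrals.h, rd.gamma))
            + 0.5 * float(np.einsum("pqrs,pqrs->", integrals.g, rd.Gamma))
        )
        u_pol, _ = polarization(gamma)
        G_new = e_exp + u_pol
        if abs(G_new - G) < conv:
            return G_new, v, sec
        G = G_new
    raise RuntimeError(f"self-consistent FCI-PCM not converged (last G {G:.10f})")
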