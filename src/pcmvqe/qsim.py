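"""Statevector simulation of particle-conserving excitation circuits.

Conventions
-----------
Qubit ``k`` encodes spin-orbital ``k``; spin-orbitals are interleaved
(orbital p alpha -> 2p, beta -> 2p+1).  Bit ``k`` of a computational basis
index is the occupation of spin-orbital ``k`` (little-endian).

Excitation gates are Givens rotations acting on the two- (single) or four-
qubit (double) occupation subspace; interior Jordan-Wigner parities are not
applied inside the gate, matching the usual particle-conserving gate set.
RDM measurement, in contrast, uses full Jordan-Wigner parity strings, so all
measured quantities are exactly fermionic.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .solvent_coupling import Rdms


def hf_state(n_qubits: int, n_electrons: int) -> np.ndarray:
    """|1...1 0...0> with the first ``n_electrons`` qubits occupied."""
    if not 0 <= n_electrons <= n_qubits:
        raise ValueError("electron count outside [0, n_qubits]")
    state = np.zeros(2**n_qubits, dtype=complex)
    state[(1 << n_electrons) - 1] = 1.0
    return state


@dataclass(frozen=True)
class Excitation:
    """A particle-conserving Givens rotation: occupied wires, then virtual."""

    kind: str                 # "single" | "double"
    wires: tuple[int, ...]    # (i, a) or (i, j, a, b)
    theta: float = 0.0

    def __post_init__(self) -> None:
        expected = 2 if self.kind == "single" else 4
        if self.kind not in ("single", "double"):
            raise ValueError(f"unknown excitation kind {self.kind!r}")
        if len(self.wires) != expected or len(set(self.wires)) != expected:
            raise ValueError(f"{self.kind} excitation needs {expected} distinct wires")


def _subspace_masks(exc: Excitation, n_qubits: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the 'occupied' pattern and their rotation partners."""
    idx = np.arange(2**n_qubits)
    if exc.kind == "single":
        occ_wires, virt_wires = exc.wires[:1], exc.wires[1:]
    else:
        occ_wires, virt_wires = exc.wires[:2], exc.wires[2:]
    occ_mask = sum(1 << w for w in occ_wires)
    virt_mask = sum(1 << w for w in virt_wires)
    sel = (idx & occ_mask) == occ_mask
    sel &= (idx & virt_mask) == 0
    src = idx[sel]                       # |1(occ) 0(virt)> pattern
    return src, src ^ occ_mask ^ virt_mask


def apply_excitation(state: np.ndarray, exc: Excitation,
                     theta: float | None = None) -> np.ndarray:
    """Rotate the excitation subspace by G(theta); norm preserved exactly.

    Also accepts a 2-D array (e.g. a density matrix), acting on its rows.
    """
    n_qubits = int(np.log2(state.shape[0]))
    theta = exc.theta if theta is None else theta
    src, dst = _subspace_masks(exc, n_qubits)
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    out = state.copy()
    out[dst] = c * state[dst] + s * state[src]
    out[src] = c * state[src] - s * state[dst]
    return out


def apply_excitation_derivative(state: np.ndarray, exc: Excitation,
                                theta: float) -> np.ndarray:
    """d/dtheta of apply_excitation; zero outside the rotated subspace."""
    n_qubits = int(np.log2(state.shape[0]))
    src, dst = _subspace_masks(exc, n_qubits)
    c, s = 0.5 * np.cos(theta / 2.0), 0.5 * np.sin(theta / 2.0)
    out = np.zeros_like(state)
    out[dst] = -s * state[dst] + c * state[src]
    out[src] = -s * state[src] - c * state[dst]
    return out


@dataclass
class Ansatz:
    """An ordered excitation list applied to the Hartree-Fock reference."""

    n_qubits: int
    n_electrons: int
    excitations: list[Excitation] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return len(self.excitations)

    def with_angles(self, theta: np.ndarray) -> "Ansatz":
        return Ansatz(
            self.n_qubits, self.n_electrons,
            [replace(e, theta=float(t)) for e, t in zip(self.excitations, theta)],
        )

    def prepare(self, theta: np.ndarray | None = None) -> np.ndarray:
        state = hf_state(self.n_qubits, self.n_electrons)
        angles = [e.theta for e in self.excitations] if theta is None else theta
        for exc, t in zip(self.excitations, angles):
            state = apply_excitation(state, exc, float(t))
        return state


# ---------------------------------------------------------------------------
# Jordan-Wigner fermionic operators on statevectors (full parity strings)
# ---------------------------------------------------------------------------

def apply_a_dag_a(state: np.ndarray, p: int, q: int) -> np.ndarray:
    """a^dag_p a_q |psi> with Jordan-Wigner phases (spin-orbital indices)."""
    idx = np.arange(state.size)
    if p == q:
        return state * ((idx >> p) & 1)
    sel = (((idx >> q) & 1) == 1) & (((idx >> p) & 1) == 0)
    src = idx[sel]
    below_q = (1 << q) - 1
    below_p = (1 << p) - 1
    sign_q = 1 - 2 * (np.bitwise_count(src & below_q).astype(np.int64) & 1)
    mid = src ^ (1 << q)
    sign_p = 1 - 2 * (np.bitwise_count(mid & below_p).astype(np.int64) & 1)
    out = np.zeros_like(state)
    out[mid ^ (1 << p)] = (sign_q * sign_p) * state[src]
    return out


def apply_e_pq(state: np.ndarray, p: int, q: int) -> np.ndarray:
    """Singlet excitation E_pq = sum_sigma a^dag_{p sigma} a_{q sigma}
    (spatial-orbital indices, interleaved spin convention)."""
    return apply_a_dag_a(state, 2 * p, 2 * q) + apply_a_dag_a(state, 2 * p + 1, 2 * q + 1)


def excitation_vectors(state: np.ndarray, n_spatial: int) -> np.ndarray:
    """Stack of E_pq |psi> for all spatial (p, q); shape (n, n, dim)."""
    dim = state.size
    out = np.empty((n_spatial, n_spatial, dim), dtype=state.dtype)
    for p in range(n_spatial):
        for q in range(n_spatial):
            out[p, q] = apply_e_pq(state, p, q)
    return out


def measure_rdms(state: np.ndarray, n_spatial: int) -> Rdms:
    """Exact spatial-orbital 1- and 2-RDMs of a statevector.

    gamma_pq = <E_pq>, Gamma_pqrs = <E_pq E_rs - d_qr E_ps>; operators carry
    full Jordan-Wigner parity strings.
    """
    if state.size != 2 ** (2 * n_spatial):
        raise ValueError("state size does not match 2 spin-orbitals per spatial orbital")
    evec = excitation_vectors(state, n_spatial)
    gamma = np.einsum("d,pqd->pq", state.conj(), evec)
    Gamma = np.einsum("qpd,rsd->pqrs", evec.conj(), evec)
    Gamma -= np.einsum("qr,ps->pqrs", np.eye(n_spatial), gamma)
    if max(np.abs(gamma.imag).max(), np.abs(Gamma.imag).max()) > 1e-9:
        raise ValueError("RDMs have a non-negligible imaginary part")
    return Rdms(gamma.real.copy(), Gamma.real.copy())
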