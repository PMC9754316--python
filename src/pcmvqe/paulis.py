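"""Pauli-string algebra for Jordan-Wigner mapped fermionic operators.

A term is stored in X-Z normal form ``coeff * X^x Z^z`` with bitmask
exponents; the Hermitian Pauli string (with Y on overlapping bits) is
``i^{|x & z|} X^x Z^z``.  This is all that is needed to count, evaluate and
shot-sample the measurement strings of molecular observables.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _popcount(x: int) -> int:
    return bin(x).count("1")


class PauliSum:
    """Sparse sum of X-Z normal-form Pauli terms keyed by (x_mask, z_mask)."""

    __slots__ = ("terms",)

    def __init__(self, terms: dict[tuple[int, int], complex] | None = None):
        self.terms = dict(terms or {})

    @classmethod
    def identity(cls, coeff: complex = 1.0) -> "PauliSum":
        return cls({(0, 0): coeff})

    @classmethod
    def annihilation(cls, k: int) -> "PauliSum":
        below = (1 << k) - 1
        return cls({(1 << k, below): 0.5, (1 << k, below | (1 << k)): -0.5})

    @classmethod
    def creation(cls, k: int) -> "PauliSum":
        below = (1 << k) - 1
        return cls({(1 << k, below): 0.5, (1 << k, below | (1 << k)): 0.5})

    def __add__(self, other: "PauliSum") -> "PauliSum":
        out = dict(self.terms)
        for key, c in other.terms.items():
            out[key] = out.get(key, 0.0) + c
        return PauliSum(out)

    def __mul__(self, other):
        if np.isscalar(other):
            return PauliSum({k: c * other for k, c in self.terms.items()})
        out: dict[tuple[int, int], complex] = {}
        for (x1, z1), c1 in self.terms.items():
            for (x2, z2), c2 in other.terms.items():
                sign = -1.0 if (_popcount(z1 & x2) & 1) else 1.0
                key = (x1 ^ x2, z1 ^ z2)
                out[key] = out.get(key, 0.0) + sign * c1 * c2
        return PauliSum(out)

    __rmul__ = __mul__

    def cleaned(self, tol: float = 1e-12) -> "PauliSum":
        return PauliSum({k: c for k, c in self.terms.items() if abs(c) > tol})

    def hermitian_strings(self) -> dict[tuple[int, int], float]:
        """Coefficients on Hermitian strings S_{x,z} = i^{|x&z|} X^x Z^z."""
        out = {}
        for (x, z), c in self.cleaned().terms.items():
            coeff = c * (-1j) ** (_popcount(x & z) % 4)
            if abs(coeff.imag) > 1e-9:
                raise ValueError("operator is not Hermitian")
            out[(x, z)] = float(coeff.real)
        return out


def apply_pauli_string(state: np.ndarray, x: int, z: int) -> np.ndarray:
    """Hermitian string S_{x,z} applied to a statevector."""
    idx = np.arange(state.size)
    phase = (1j) ** (_popcount(x & z) % 4)
    signs = 1 - 2 * (np.bitwise_count((idx ^ x) & z).astype(np.int64) & 1)
    return phase * signs * state[idx ^ x]


def pauli_expectation(state: np.ndarray, x: int, z: int) -> float:
    return float(np.real(np.vdot(state, apply_pauli_string(state, x, z))))


def e_pq_operator(p: int, q: int) -> PauliSum:
    """JW image of the singlet excitation E_pq (interleaved spin ordering)."""
    op = PauliSum()
    for spin in (0, 1):
        op = op + PauliSum.creation(2 * p + spin) * PauliSum.annihilation(2 * q + spin)
    return op.cleaned()


def one_rdm_operators(n_spatial: int) -> dict[tuple[int, int], PauliSum]:
    """Hermitized 1-RDM observables (E_pq + E_qp)/2-style, p <= q."""
    out = {}
    for p in range(n_spatial):
        for q in range(p + 1):
            op = e_pq_operator(p, q)
            if p != q:
                op = (op + e_pq_operator(q, p)) * 0.5
            out[(p, q)] = op.cleaned()
    return out


def hamiltonian_operator(h: np.ndarray, g: np.ndarray, e_offset: float) -> PauliSum:
    """JW image of the spin-free molecular Hamiltonian (chemists' g ordering).

    H = E_off + sum_pq h~_pq E_pq + 1/2 sum_pqrs g_pqrs E_pq E_rs with the
    delta-contraction folded into h~_pq = h_pq - 1/2 sum_r g_prrq.
    """
    n = h.shape[0]
    h_eff = h - 0.5 * np.einsum("prrq->pq", g)
    total = PauliSum.identity(e_offset)
    e_ops = [[e_pq_operator(p, q) for q in range(n)] for p in range(n)]
    for p in range(n):
        for q in range(n):
            if abs(h_eff[p, q]) > 1e-12:
                total = total + e_ops[p][q] * h_eff[p, q]
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    c = 0.5 * g[p, q, r, s]
                    if abs(c) > 1e-12:
                        total = total + (e_ops[p][q] * e_ops[r][s]) * c
    return total.cleaned()


@dataclass
class MeasuredOperator:
    """An observable resolved into Hermitian Pauli strings for sampling."""

    strings: dict[tuple[int, int], float]

    @property
    def n_strings(self) -> int:
        """Number of non-identity strings to measure."""
        return sum(1 for (x, z) in self.strings if (x, z) != (0, 0))

    def expectation(self, state: np.ndarray) -> float:
        return sum(
            c * (1.0 if (x, z) == (0, 0) else pauli_expectation(state, x, z))
            for (x, z), c in self.strings.items()
        )

    @classmethod
    def from_sum(cls, op: PauliSum) -> "MeasuredOperator":
        return cls(op.hermitian_strings())
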