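"""Gaussian one- and two-electron integrals (McMurchie-Davidson scheme).

The engine expands every primitive product into Hermite Gaussians
(E-coefficients) and evaluates Coulomb-type integrals with Boys-function
based Hermite-Coulomb recursions.  It supports s and p shells, which is all
a minimal STO-3G basis over H..O requires.  All quantities are in Hartree
atomic units; electron-repulsion integrals use chemists' ordering (pq|rs).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import hyp1f1

from .basis import AtomicOrbital, GaussianBasis
from .geometry import Geometry, nuclear_repulsion


def boys(n: int, x: np.ndarray) -> np.ndarray:
    """Boys function F_n(x), vectorized; exact limit F_n(0) = 1/(2n+1)."""
    x = np.asarray(x, dtype=float)
    return hyp1f1(n + 0.5, n + 1.5, -x) / (2.0 * n + 1.0)


@lru_cache(maxsize=200000)
def _e_coeff(i: int, j: int, t: int, Qx: float, a: float, b: float) -> float:
    """Hermite expansion coefficient E_t^{ij} for a 1-D primitive pair."""
    p = a + b
    q = a * b / p
    if t < 0 or t > i + j:
        return 0.0
    if i == j == t == 0:
        return float(np.exp(-q * Qx * Qx))
    if j == 0:
        return (
            _e_coeff(i - 1, j, t - 1, Qx, a, b) / (2 * p)
            - (q * Qx / a) * _e_coeff(i - 1, j, t, Qx, a, b)
            + (t + 1) * _e_coeff(i - 1, j, t + 1, Qx, a, b)
        )
    return (
        _e_coeff(i, j - 1, t - 1, Qx, a, b) / (2 * p)
        + (q * Qx / b) * _e_coeff(i, j - 1, t, Qx, a, b)
        + (t + 1) * _e_coeff(i, j - 1, t + 1, Qx, a, b)
    )


class _HermiteCoulomb:
    """Hermite-Coulomb integrals R_{tuv}(p, PC), vectorized over points."""

    def __init__(self, p: np.ndarray, PC: np.ndarray, n_max: int):
        self.p = p
        self.PC = PC
        T = p * np.einsum("...i,...i->...", PC, PC)
        self._F = [boys(n, T) for n in range(n_max + 1)]
        self._memo: dict[tuple[int, int, int, int], np.ndarray] = {}

    def R(self, t: int, u: int, v: int, n: int = 0) -> np.ndarray:
        if t < 0 or u < 0 or v < 0:
            return 0.0
        key = (t, u, v, n)
        if key in self._memo:
            return self._memo[key]
        if t == u == v == 0:
            out = (-2.0 * self.p) ** n * self._F[n]
        elif t > 0:
            out = (t - 1) * self.R(t - 2, u, v, n + 1) + self.PC[..., 0] * self.R(t - 1, u, v, n + 1)
        elif u > 0:
            out = (u - 1) * self.R(t, u - 2, v, n + 1) + self.PC[..., 1] * self.R(t, u - 1, v, n + 1)
        else:
            out = (v - 1) * self.R(t, u, v - 2, n + 1) + self.PC[..., 2] * self.R(t, u, v - 1, n + 1)
        self._memo[key] = out
        return out


@dataclass
class _PairData:
    """Hermite expansion of the product density of one contracted AO pair."""

    p: np.ndarray          # (K,) combined exponents over primitive pairs
    P: np.ndarray          # (K, 3) product centers
    coef: np.ndarray       # (K,) contraction coefficient products
    tuv: list[tuple[int, int, int]]
    lam: np.ndarray        # (K, n_tuv) Hermite coefficients E_t E_u E_v
    L: int                 # total angular momentum of the pair


def _pair_data(ao1: AtomicOrbital, ao2: AtomicOrbital) -> _PairData:
    A, B = ao1.center, ao2.center
    Q = A - B
    l1, l2 = ao1.lmn, ao2.lmn
    L = ao1.total_angular_momentum + ao2.total_angular_momentum
    tuv = [
        (t, u, v)
        for t in range(l1[0] + l2[0] + 1)
        for u in range(l1[1] + l2[1] + 1)
        for v in range(l1[2] + l2[2] + 1)
    ]
    ps, Ps, coefs, lams = [], [], [], []
    for ka, a in enumerate(ao1.exponents):
        for kb, b in enumerate(ao2.exponents):
            p = a + b
            ps.append(p)
            Ps.append((a * A + b * B) / p)
            coefs.append(ao1.coefficients[ka] * ao2.coefficients[kb])
            lams.append(
                [
                    _e_coeff(l1[0], l2[0], t, Q[0], a, b)
                    * _e_coeff(l1[1], l2[1], u, Q[1], a, b)
                    * _e_coeff(l1[2], l2[2], v, Q[2], a, b)
                    for (t, u, v) in tuv
                ]
            )
    return _PairData(np.array(ps), np.array(Ps), np.array(coefs), tuv, np.array(lams), L)


def _overlap_1d(i: int, j: int, Qx: float, a: float, b: float) -> float:
    return _e_coeff(i, j, 0, Qx, a, b) * np.sqrt(np.pi / (a + b))


def _kinetic_1d(i: int, j: int, Qx: float, a: float, b: float) -> float:
    t = -2.0 * b * b * _overlap_1d(i, j + 2, Qx, a, b)
    t += b * (2 * j + 1) * _overlap_1d(i, j, Qx, a, b)
    if j >= 2:
        t -= 0.5 * j * (j - 1) * _overlap_1d(i, j - 2, Qx, a, b)
    return t


def _overlap_kinetic(ao1: AtomicOrbital, ao2: AtomicOrbital) -> tuple[float, float]:
    Q = ao1.center - ao2.center
    s_tot, t_tot = 0.0, 0.0
    for ka, a in enumerate(ao1.exponents):
        for kb, b in enumerate(ao2.exponents):
            c = ao1.coefficients[ka] * ao2.coefficients[kb]
            s1 = [_overlap_1d(ao1.lmn[d], ao2.lmn[d], Q[d], a, b) for d in range(3)]
            t1 = [_kinetic_1d(ao1.lmn[d], ao2.lmn[d], Q[d], a, b) for d in range(3)]
            s_tot += c * s1[0] * s1[1] * s1[2]
            t_tot += c * (
                t1[0] * s1[1] * s1[2] + s1[0] * t1[1] * s1[2] + s1[0] * s1[1] * t1[2]
            )
    return s_tot, t_tot


def _coulomb_at_points(pair: _PairData, points: np.ndarray) -> np.ndarray:
    """integral chi_p chi_q / |r - s_i| d3r for every point s_i (bohr)."""
    # broadcast primitive pairs (K) against points (M)
    PC = pair.P[:, None, :] - points[None, :, :]          # (K, M, 3)
    p = pair.p[:, None]
    rt = _HermiteCoulomb(p, PC, pair.L)
    acc = np.zeros((len(pair.p), points.shape[0]))
    for idx, (t, u, v) in enumerate(pair.tuv):
        lam = pair.lam[:, idx]
        if np.all(lam == 0.0):
            continue
        acc += lam[:, None] * rt.R(t, u, v)
    acc *= (2.0 * np.pi / p) * pair.coef[:, None]
    return acc.sum(axis=0)


def _eri_quartet(p1: _PairData, p2: _PairData) -> float:
    K1, K2 = len(p1.p), len(p2.p)
    pa = p1.p[:, None]
    pb = p2.p[None, :]
    alpha = pa * pb / (pa + pb)
    PQ = p1.P[:, None, :] - p2.P[None, :, :]
    rt = _HermiteCoulomb(alpha, PQ, p1.L + p2.L)
    # R stacked over (tuv of bra, tuv of ket)
    Rstack = np.empty((len(p1.tuv), len(p2.tuv), K1, K2))
    for i, (t, u, v) in enumerate(p1.tuv):
        for j, (tt, uu, vv) in enumerate(p2.tuv):
            sign = -1.0 if (tt + uu + vv) % 2 else 1.0
            Rstack[i, j] = sign * rt.R(t + tt, u + uu, v + vv)
    pref = 2.0 * np.pi**2.5 / (pa * pb * np.sqrt(pa + pb))
    pref = pref * p1.coef[:, None] * p2.coef[None, :]
    return float(np.einsum("ki,lj,ijkl->", p1.lam, p2.lam, Rstack * pref, optimize=True))


@dataclass
class CoreIntegrals:
    """AO-basis integrals of the gas-phase molecular Hamiltonian."""

    overlap: np.ndarray
    kinetic: np.ndarray
    nuclear_attraction: np.ndarray
    eri: np.ndarray  # chemists' (pq|rs)
    e_nn: float
    n_ao: int


def _all_pairs(basis: GaussianBasis) -> list[list[_PairData]]:
    n = basis.n_ao
    pairs: list[list[_PairData]] = [[None] * n for _ in range(n)]  # type: ignore
    for i in range(n):
        for j in range(i + 1):
            pd = _pair_data(basis.aos[i], basis.aos[j])
            pairs[i][j] = pd
            pairs[j][i] = pd
    return pairs


def core_integrals(basis: GaussianBasis, geometry: Geometry) -> CoreIntegrals:
    """Overlap, kinetic, nuclear-attraction and ERI tensors plus E_nn."""
    n = basis.n_ao
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    nuclei = geometry.coords_bohr
    Z = geometry.charges
    pairs = _all_pairs(basis)
    for i in range(n):
        for j in range(i + 1):
            s, t = _overlap_kinetic(basis.aos[i], basis.aos[j])
            S[i, j] = S[j, i] = s
            T[i, j] = T[j, i] = t
            v = -np.dot(Z, _coulomb_at_points(pairs[i][j], nuclei))
            V[i, j] = V[j, i] = v

    eri = np.zeros((n, n, n, n))
    pair_index = [(i, j) for i in range(n) for j in range(i + 1)]
    for a, (i, j) in enumerate(pair_index):
        for b in range(a + 1):
            k, l = pair_index[b]
            val = _eri_quartet(pairs[i][j], pairs[k][l])
            for (pp, qq) in ((i, j), (j, i)):
                for (rr, ss) in ((k, l), (l, k)):
                    eri[pp, qq, rr, ss] = val
                    eri[rr, ss, pp, qq] = val
    return CoreIntegrals(S, T, V, eri, nuclear_repulsion(geometry), n)


def electronic_potential_integrals(basis: GaussianBasis, points: np.ndarray) -> np.ndarray:
    """Potential of the elementary electronic density -chi_p chi_q at each point.

    Returns ``K[p, q, i] = -int chi_p(r) chi_q(r) / |r - s_i| d3r`` with points
    in bohr; the minus sign folds in the electron charge.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = basis.n_ao
    K = np.zeros((n, n, points.shape[0]))
    for i in range(n):
        for j in range(i + 1):
            val = -_coulomb_at_points(_pair_data(basis.aos[i], basis.aos[j]), points)
            K[i, j] = val
            K[j, i] = val
    if not np.all(np.isfinite(K)):
        raise FloatingPointError("non-finite electronic potential integral")
    return K
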