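"""Contracted Gaussian basis sets (STO-3G tables for H through O, s/p shells).

Each atomic orbital is a contracted Cartesian Gaussian
``chi(r) = sum_k c_k N_k (x-Ax)^l (y-Ay)^m (z-Az)^n exp(-a_k |r-A|^2)``
with the contraction rescaled so that every AO has unit self-overlap.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .geometry import Geometry

_P_LMN = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]


class UnsupportedElementError(ValueError):
    pass


@dataclass
class Shell:
    atom_index: int
    angular_momentum: int  # 0 = s, 1 = p
    exponents: np.ndarray
    coefficients: np.ndarray  # raw contraction coefficients (basis-table values)


@dataclass
class AtomicOrbital:
    """One contracted Cartesian Gaussian; coefficients include primitive norms."""

    center: np.ndarray  # bohr
    lmn: tuple[int, int, int]
    exponents: np.ndarray
    coefficients: np.ndarray

    @property
    def total_angular_momentum(self) -> int:
        return sum(self.lmn)


@dataclass
class GaussianBasis:
    shells: list[Shell]
    aos: list[AtomicOrbital]

    @property
    def n_ao(self) -> int:
        return len(self.aos)


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def _primitive_norm(alpha: float, lmn) -> float:
    l, m, n = lmn
    L = l + m + n
    pref = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (L / 2.0)
    return pref / np.sqrt(
        _double_factorial(2 * l - 1) * _double_factorial(2 * m - 1) * _double_factorial(2 * n - 1)
    )


def _primitive_pair_overlap(a, lmn_a, b, lmn_b) -> float:
    # same-center primitives only (used for contraction normalization)
    p = a + b
    val = (np.pi / p) ** 1.5
    for la, lb in zip(lmn_a, lmn_b):
        L = la + lb
        if L % 2 == 1:
            return 0.0
        val *= _double_factorial(L - 1) / (2.0 * p) ** (L // 2)
    return val


def _load_sto3g() -> dict:
    with resources.files("pcmvqe.data").joinpath("sto3g.json").open() as fh:
        return json.load(fh)


_STO3G = None


def build_basis(geometry: Geometry, basis_name: str = "STO-3G") -> GaussianBasis:
    """Assign basis shells and normalized contracted AOs to every atom."""
    global _STO3G
    if basis_name.upper().replace(" ", "") != "STO-3G":
        raise ValueError(f"unsupported basis {basis_name!r}; only STO-3G is tabulated")
    if _STO3G is None:
        _STO3G = _load_sto3g()
    table = _STO3G
    shells: list[Shell] = []
    aos: list[AtomicOrbital] = []
    centers_bohr = geometry.coords_bohr
    for i, symbol in enumerate(geometry.symbols):
        if symbol not in table["elements"]:
            raise UnsupportedElementError(f"element {symbol!r} not in the STO-3G table")
        for kind, coef_key, exps in table["elements"][symbol]["shells"]:
            am = 0 if kind == "s" else 1
            exps = np.asarray(exps, dtype=float)
            coefs = np.asarray(table["coefficients"][coef_key], dtype=float)
            shells.append(Shell(i, am, exps, coefs))
            lmns = [(0, 0, 0)] if am == 0 else _P_LMN
            for lmn in lmns:
                norms = np.array([_primitive_norm(a, lmn) for a in exps])
                c = coefs * norms
                # rescale to unit self-overlap
                self_ov = 0.0
                for ka in range(len(exps)):
                    for kb in range(len(exps)):
                        self_ov += c[ka] * c[kb] * _primitive_pair_overlap(
                            exps[ka], lmn, exps[kb], lmn
                        )
                c = c / np.sqrt(self_ov)
                aos.append(AtomicOrbital(centers_bohr[i].copy(), lmn, exps.copy(), c))
    return GaussianBasis(shells, aos)
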