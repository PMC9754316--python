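"""Discretized IEF-PCM operators and the solvent response matrix.

On the tessellated cavity the Calderon-projector components become matrices:
``S`` (single-layer, potential of a unit tessera charge), ``D`` (double-layer,
normal field), and the diagonal area matrix ``A``.  The response matrix maps
the molecular electrostatic potential sampled at tessera centers to the
apparent surface charges:

    q = Q V,   Q = -[2 pi f_eps I - D A]^-1 (2 pi I - D A) S^-1,
    f_eps = (eps + 1) / (eps - 1).

``Q`` is symmetrized; the symmetric form makes the electrostatic free energy a
clean quadratic form (1/2 V^T Q V) and the nuclear/electronic couplings obey
j = y exactly.  Diagonal elements use the canonical collocation choices
S_ii = 1.0694 sqrt(4 pi / a_i) and the closed-surface sum rule for D_ii.
"""
from __future__ import annotations

import numpy as np

from .cavity import Cavity


def build_SDA(cavity: Cavity) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-layer S, double-layer D and diagonal area matrix A."""
    s = cavity.centers
    a = cavity.areas
    n = cavity.normals
    diff = s[None, :, :] - s[:, None, :]          # diff[i, j] = s_j - s_i
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, 1.0)
    if np.any(dist < 1e-10):
        raise ValueError("coincident tesserae")

    S = 1.0 / dist
    np.fill_diagonal(S, 1.0694 * np.sqrt(4.0 * np.pi / a))

    # normal-derivative (double-layer) kernel D_ij = n_j.(s_i - s_j)/r^3
    D = -np.einsum("ijk,jk->ij", diff, n) / dist**3
    np.fill_diagonal(D, 0.0)
    # closed-surface sum rule: sum_j D_ij a_j = -2 pi fixes the diagonal
    np.fill_diagonal(D, -(2.0 * np.pi + D @ a) / a)

    A = np.diag(a)
    return S, D, A


def response_matrix(S: np.ndarray, D: np.ndarray, A: np.ndarray,
                    epsilon: float) -> np.ndarray:
    """Solvent response matrix Q (charge per unit potential), symmetrized.

    ``epsilon = 1`` returns the zero matrix (vacuum limit).
    """
    n = S.shape[0]
    if epsilon == 1.0:
        return np.zeros_like(S)
    if epsilon < 1.0:
        raise ValueError("epsilon must be >= 1")
    f_eps = (epsilon + 1.0) / (epsilon - 1.0)
    DA = D * np.diag(A)[None, :]
    lhs = 2.0 * np.pi * f_eps * np.eye(n) - DA
    cond = np.linalg.cond(lhs)
    if cond > 1e12:
        raise np.linalg.LinAlgError(f"singular IEF system matrix (cond {cond:.2e})")
    rhs = 2.0 * np.pi * np.eye(n) - DA
    Q_raw = -np.linalg.solve(lhs, rhs @ np.linalg.inv(S))
    return 0.5 * (Q_raw + Q_raw.T)


def apply_response(Q: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Apparent surface charges q = Q V for a sampled potential V."""
    V = np.asarray(V, dtype=float)
    if V.shape[-1] != Q.shape[1]:
        raise ValueError(f"potential length {V.shape[-1]} != N_tess {Q.shape[1]}")
    return Q @ V
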