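"""Statevector gates, Jordan-Wigner operators and RDM measurement."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from pcmvqe.paulis import (MeasuredOperator, PauliSum, hamiltonian_operator)
from pcmvqe.qsim import (Ansatz, Excitation, apply_a_dag_a, apply_excitation,
                         apply_excitation_derivative, hf_state, measure_rdms)


def test_hf_state_occupations():
    s = hf_state(6, 2)
    assert s[0b000011] == 1.0 and np.abs(s).sum() == 1.0
    s0 = hf_state(4, 0)
    assert s0[0] == 1.0
    with pytest.raises(ValueError):
        hf_state(4, 5)
    # total occupation expectation equals the electron count
    idx = np.arange(64)
    occ = np.bitwise_count(idx).astype(float)
    assert (np.abs(hf_state(6, 2)) ** 2 @ occ) == pytest.approx(2.0)


def test_single_excitation_theta_zero_and_pi():
    s = hf_state(4, 2)
    exc = Excitation("single", (1, 3))
    np.testing.assert_allclose(apply_excitation(s, exc, 0.0), s)
    flipped = apply_excitation(s, exc, np.pi)
    # |0011> -> occupation moved from wire 1 to wire 3 up to a sign
    assert abs(flipped[0b1001]) == pytest.approx(1.0)


def test_double_excitation_rotates_paired_occupations():
    s = hf_state(4, 2)
    exc = Excitation("double", (0, 1, 2, 3))
    th = 0.7
    out = apply_excitation(s, exc, th)
    assert out[0b0011] == pytest.approx(np.cos(th / 2))
    assert abs(out[0b1100]) == pytest.approx(abs(np.sin(th / 2)))
    assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)


def test_invalid_excitations_rejected():
    with pytest.raises(ValueError):
        Excitation("single", (1, 1))
    with pytest.raises(ValueError):
        Excitation("double", (0, 1, 2))
    with pytest.raises(ValueError):
        Excitation("triple", (0, 1, 2))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 10**6), st.floats(-np.pi, np.pi))
def test_gates_conserve_norm_and_particle_number(seed, theta):
    rng = np.random.default_rng(seed)
    n = 6
    state = rng.normal(size=2**n) + 1j * rng.normal(size=2**n)
    state /= np.linalg.norm(state)
    wires = tuple(rng.choice(n, size=4, replace=False))
    exc = (Excitation("double", wires) if seed % 2 else
           Excitation("single", wires[:2]))
    out = apply_excitation(state, exc, theta)
    assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)
    idx = np.arange(2**n)
    occ = np.bitwise_count(idx).astype(float)
    before = float(np.abs(state) ** 2 @ occ)
    after = float(np.abs(out) ** 2 @ occ)
    assert after == pytest.approx(before, abs=1e-10)


def _dense_hermitian(op: PauliSum, n_qubits: int) -> np.ndarray:
    from pcmvqe.paulis import apply_pauli_string

    dim = 2**n_qubits
    mat = np.zeros((dim, dim), dtype=complex)
    for (x, z), c in MeasuredOperator.from_sum(op).strings.items():
        cols = np.array([apply_pauli_string(e, x, z) for e in np.eye(dim, dtype=complex)]).T
        mat += c * cols
    return mat


def test_adjacent_gate_matches_fermionic_exponential():
    """For adjacent wires the Givens gate equals expm of the JW-mapped
    anti-Hermitian single-excitation generator."""
    n = 4
    p, q = 2, 3  # adjacent wires: no interior parity string
    gen_h = (PauliSum.creation(p) * PauliSum.annihilation(q)
             + PauliSum.creation(q) * PauliSum.annihilation(p) * (-1.0)) * 1j
    K = -1j * _dense_hermitian(gen_h, n)   # a+_p a_q - a+_q a_p
    rng = np.random.default_rng(7)
    psi = rng.normal(size=2**n) + 1j * rng.normal(size=2**n)
    psi /= np.linalg.norm(psi)
    th = 0.61
    exc = Excitation("single", (q, p))
    gate = apply_excitation(psi, exc, th)
    for sign in (+1.0, -1.0):
        U = expm(sign * (th / 2) * K)
        if np.allclose(U @ psi, gate, atol=1e-10):
            break
    else:
        raise AssertionError("gate does not match the fermionic exponential")


def test_gate_derivative_matches_finite_difference():
    psi = hf_state(4, 2)
    exc = Excitation("double", (0, 1, 2, 3))
    th, h = 0.37, 1e-6
    d = apply_excitation_derivative(psi, exc, th)
    fd = (apply_excitation(psi, exc, th + h) - apply_excitation(psi, exc, th - h)) / (2 * h)
    np.testing.assert_allclose(d, fd, atol=1e-8)


def test_measured_rdms_on_hf_state():
    rd = measure_rdms(hf_state(6, 4), 3)
    np.testing.assert_allclose(rd.gamma, np.diag([2.0, 2.0, 0.0]), atol=1e-12)
    assert np.trace(rd.gamma) == pytest.approx(4.0)


def _random_ansatz_state(seed, n_spatial=3, n_electrons=2):
    rng = np.random.default_rng(seed)
    nq = 2 * n_spatial
    ansatz = Ansatz(nq, n_electrons, [
        Excitation("double", (0, 1, 2, 3)),
        Excitation("double", (0, 1, 4, 5)),
        Excitation("single", (0, 2)),
        Excitation("single", (1, 5)),
    ])
    return ansatz.prepare(rng.uniform(-1.5, 1.5, 4)), n_spatial, n_electrons


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_rdm_contraction_identity_and_hermiticity(seed):
    state, n_sp, ne = _random_ansatz_state(seed)
    rd = measure_rdms(state, n_sp)
    np.testing.assert_allclose(rd.gamma, rd.gamma.T, atol=1e-10)
    assert np.linalg.eigvalsh(rd.gamma).min() > -1e-10
    # partial trace over the second index pair (chemists' pairing)
    contracted = np.einsum("pqrr->pq", rd.Gamma)
    np.testing.assert_allclose(contracted, (ne - 1) * rd.gamma, atol=1e-8)


@pytest.mark.parametrize("seed", [3, 11])
def test_rdm_energy_matches_dense_jw_hamiltonian(seed):
    """E from (gamma, Gamma) with (h, g) equals <psi|H|psi> computed from the
    Pauli-resolved dense Hamiltonian (independent operator route)."""
    rng = np.random.default_rng(seed)
    n_sp = 2
    h = rng.normal(size=(n_sp, n_sp))
    h = 0.5 * (h + h.T)
    g = rng.normal(size=(n_sp,) * 4)
    g = g + g.transpose(1, 0, 2, 3)
    g = g + g.transpose(0, 1, 3, 2)
    g = g + g.transpose(2, 3, 0, 1)
    e_off = rng.normal()
    ansatz = Ansatz(4, 2, [Excitation("double", (0, 1, 2, 3)),
                           Excitation("single", (0, 2))])
    psi = ansatz.prepare(rng.uniform(-1, 1, 2))
    rd = measure_rdms(psi, n_sp)
    e_rdm = e_off + np.einsum("pq,pq->", h, rd.gamma) \
        + 0.5 * np.einsum("pqrs,pqrs->", g, rd.Gamma)
    op = MeasuredOperator.from_sum(hamiltonian_operator(h, g, e_off))
    assert e_rdm == pytest.approx(op.expectation(psi), abs=1e-10)


def test_measure_rdms_rejects_odd_register():
    with pytest.raises(ValueError):
        measure_rdms(hf_state(6, 2), 2)


def test_a_dag_a_number_operator():
    psi = hf_state(4, 2)
    out = apply_a_dag_a(psi, 1, 1)
    np.testing.assert_allclose(out, psi)
    assert np.vdot(psi, apply_a_dag_a(psi, 3, 3)) == pytest.approx(0.0)
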