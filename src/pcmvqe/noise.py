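"""Shot sampling, generic noise channels, and noisy solvation estimates.

The noise model is a parameterized stand-in for hardware: depolarizing
channels after every excitation gate (single-qubit strength ``p1`` on each
touched wire, two-qubit strength ``p2`` on the rotated wire pairs) plus
independent readout bit-flips.  Error bars follow the conservative
per-string bound sigma_k = 1/sqrt(shots) propagated through the observable's
Pauli coefficients.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paulis import (MeasuredOperator, hamiltonian_operator, one_rdm_operators)
from .qsim import Ansatz, apply_excitation, hf_state
from .solvent_coupling import polarization_energy, solvation_free_energy


@dataclass
class NoiseModel:
    p1: float = 0.0         # single-qubit depolarizing probability per gate
    p2: float = 0.0         # two-qubit depolarizing probability per gate
    p_readout: float = 0.0  # per-qubit readout bit-flip probability
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p_readout"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def is_trivial(self) -> bool:
        return self.p1 == self.p2 == self.p_readout == 0.0


@dataclass
class SampledEstimate:
    mean: float
    shots: int
    sigma_bound: float


# ---------------------------------------------------------------------------
# density-matrix simulation of noisy circuits
# ---------------------------------------------------------------------------

def _pauli_phase_vector(n_qubits: int, x: int, z: int) -> np.ndarray:
    idx = np.arange(2**n_qubits)
    phase = (1j) ** (bin(x & z).count("1") % 4)
    return phase * (1 - 2 * (np.bitwise_count((idx ^ x) & z).astype(np.int64) & 1))


def _apply_pauli_density(rho: np.ndarray, x: int, z: int) -> np.ndarray:
    n_qubits = int(np.log2(rho.shape[0]))
    idx = np.arange(2**n_qubits)
    phi = _pauli_phase_vector(n_qubits, x, z)
    out = rho[np.ix_(idx ^ x, idx ^ x)]
    return out * np.outer(phi, phi.conj())


def _depolarize(rho: np.ndarray, wires: tuple[int, ...], p: float) -> np.ndarray:
    """Depolarizing channel on the given wires: with probability ``p`` the
    marginal is replaced by the maximally mixed state (full Pauli twirl)."""
    if p == 0.0:
        return rho
    paulis = []
    for mask in range(4 ** len(wires)):
        x = z = 0
        m = mask
        for w in wires:
            sel = m % 4    # 0:I 1:X 2:Y 3:Z
            m //= 4
            if sel in (1, 2):
                x |= 1 << w
            if sel in (2, 3):
                z |= 1 << w
        paulis.append((x, z))
    acc = sum(_apply_pauli_density(rho, x, z) for x, z in paulis)
    return (1.0 - p) * rho + (p / len(paulis)) * acc


def simulate_density(ansatz: Ansatz, theta: np.ndarray,
                     noise: NoiseModel | None = None) -> np.ndarray:
    """Density matrix after the (possibly noisy) state-preparation circuit."""
    n = ansatz.n_qubits
    if n > 8:
        raise ValueError("dense density-matrix simulation limited to 8 qubits")
    psi = hf_state(n, ansatz.n_electrons)
    rho = np.outer(psi, psi.conj())
    for exc, t in zip(ansatz.excitations, theta):
        rho = apply_excitation(rho, exc, float(t))            # U rho (rows)
        rho = apply_excitation(rho.conj().T, exc, float(t)).conj().T
        if noise is not None and not noise.is_trivial:
            if exc.kind == "single":
                rho = _depolarize(rho, exc.wires, noise.p2)
            else:
                rho = _depolarize(rho, exc.wires[:2], noise.p2)
                rho = _depolarize(rho, exc.wires[2:], noise.p2)
            for w in exc.wires:
                rho = _depolarize(rho, (w,), noise.p1)
    return rho


# ---------------------------------------------------------------------------
# Pauli-string measurement simulation
# ---------------------------------------------------------------------------

_H_GATE = np.array([[1.0, 1.0], [1.0, -1.0]]) / np.sqrt(2.0)
_SDG = np.diag([1.0, -1.0j])


def _apply_1q(vec_or_rho: np.ndarray, u: np.ndarray, k: int, density: bool) -> np.ndarray:
    dim = vec_or_rho.shape[0]
    idx = np.arange(dim)
    i0 = idx[(idx >> k) & 1 == 0]
    i1 = i0 | (1 << k)
    out = np.array(vec_or_rho, dtype=complex, copy=True)
    out[i0], out[i1] = (u[0, 0] * vec_or_rho[i0] + u[0, 1] * vec_or_rho[i1],
                        u[1, 0] * vec_or_rho[i0] + u[1, 1] * vec_or_rho[i1])
    if density:
        tmp = out.conj().T.copy()
        res = np.array(tmp, copy=True)
        res[i0], res[i1] = (u[0, 0] * tmp[i0] + u[0, 1] * tmp[i1],
                            u[1, 0] * tmp[i0] + u[1, 1] * tmp[i1])
        out = res.conj().T
    return out


def _parse_pauli(pauli, n_qubits: int) -> tuple[int, int]:
    if isinstance(pauli, tuple):
        return pauli
    if len(pauli) != n_qubits:
        raise ValueError(f"pauli string length {len(pauli)} != {n_qubits} qubits")
    x = z = 0
    for k, ch in enumerate(pauli.upper()):
        if ch == "X":
            x |= 1 << k
        elif ch == "Y":
            x |= 1 << k
            z |= 1 << k
        elif ch == "Z":
            z |= 1 << k
        elif ch != "I":
            raise ValueError(f"invalid Pauli letter {ch!r}")
    return x, z


def sample_pauli(state_or_density, pauli, shots: int,
                 rng: np.random.Generator, p_readout: float = 0.0) -> SampledEstimate:
    """Estimate <P> by measuring ``shots`` eigenbasis-rotated bitstrings.

    The identity string is deterministic and returns mean 1 with zero
    variance.  Readout bit-flips (probability ``p_readout`` per qubit) are
    applied to the sampled bitstrings.
    """
    if shots < 1:
        raise ValueError("shots must be >= 1")
    arr = np.asarray(state_or_density)
    density = arr.ndim == 2
    n_qubits = int(np.log2(arr.shape[0]))
    x, z = _parse_pauli(pauli, n_qubits)
    if (x, z) == (0, 0):
        return SampledEstimate(1.0, shots, 0.0)
    work = arr.astype(complex)
    for k in range(n_qubits):
        xb, zb = (x >> k) & 1, (z >> k) & 1
        if xb and zb:
            work = _apply_1q(work, _SDG, k, density)
            work = _apply_1q(work, _H_GATE, k, density)
        elif xb:
            work = _apply_1q(work, _H_GATE, k, density)
    probs = np.real(np.diagonal(work)) if density else np.abs(work) ** 2
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    outcomes = rng.choice(len(probs), size=shots, p=probs)
    if p_readout > 0.0:
        flips = np.zeros(shots, dtype=np.int64)
        for k in range(n_qubits):
            flips |= (rng.random(shots) < p_readout).astype(np.int64) << k
        outcomes = outcomes ^ flips
    support = x | z
    signs = 1 - 2 * (np.bitwise_count(outcomes & support).astype(np.int64) & 1)
    return SampledEstimate(float(signs.mean()), shots, 1.0 / np.sqrt(shots))


def apply_noise(ansatz: Ansatz, theta: np.ndarray, noise_model: NoiseModel) -> np.ndarray:
    """Noisy circuit execution; returns the mixed-state density matrix."""
    return simulate_density(ansatz, theta, noise_model)


def propagate_error_bars(term_coefficients: np.ndarray, shots: int) -> float:
    """sigma_total = sqrt(sum_k c_k^2 / shots): the per-string upper bound
    sigma_k = 1/sqrt(shots) propagated through the Pauli expansion."""
    if shots <= 0:
        raise ValueError("shots must be positive")
    c = np.asarray(term_coefficients, dtype=float)
    return float(np.sqrt(np.sum(c**2) / shots))


def normalize_rdm_trace(gamma: np.ndarray, n_electrons: int) -> np.ndarray:
    """Rescale a sampled 1-RDM so its trace is exactly the electron count."""
    tr = float(np.trace(gamma))
    if tr <= 0:
        raise ValueError(f"non-positive 1-RDM trace {tr}")
    return gamma * (n_electrons / tr)


def trace_distance_rdm(gamma1: np.ndarray, gamma2: np.ndarray,
                       n_electrons: int) -> float:
    """D = Tr|g1 - g2| / (2 N_e), in [0, 1]; 1 for orthogonal supports."""
    g1, g2 = np.asarray(gamma1), np.asarray(gamma2)
    if g1.shape != g2.shape:
        raise ValueError("1-RDM shape mismatch")
    sv = np.linalg.eigvalsh(0.5 * ((g1 - g2) + (g1 - g2).conj().T))
    return float(np.abs(sv).sum() / (2.0 * n_electrons))


# ---------------------------------------------------------------------------
# sampled estimators and the noisy solvation experiment
# ---------------------------------------------------------------------------

class SampledObservables:
    """Measure a set of observables by sampling each distinct Pauli string."""

    def __init__(self, n_spatial: int, h: np.ndarray, g: np.ndarray, e_offset: float):
        self.n_spatial = n_spatial
        self.hamiltonian = MeasuredOperator.from_sum(hamiltonian_operator(h, g, e_offset))
        self.rdm_ops = {key: MeasuredOperator.from_sum(op)
                        for key, op in one_rdm_operators(n_spatial).items()}
        self.rdm_strings = sorted({s for op in self.rdm_ops.values() for s in op.strings})

    def n_hamiltonian_strings(self) -> int:
        return self.hamiltonian.n_strings

    def n_rdm_strings(self) -> int:
        return sum(1 for s in self.rdm_strings if s != (0, 0))

    def _string_means(self, rho, strings, shots, rng, p_readout):
        return {s: sample_pauli(rho, s, shots, rng, p_readout).mean if s != (0, 0) else 1.0
                for s in strings}

    def sampled_energy(self, rho, shots, rng, p_readout=0.0) -> float:
        means = self._string_means(rho, self.hamiltonian.strings, shots, rng, p_readout)
        return float(sum(c * means[s] for s, c in self.hamiltonian.strings.items()))

    def sampled_gamma(self, rho, shots, rng, p_readout=0.0) -> np.ndarray:
        means = self._string_means(rho, self.rdm_strings, shots, rng, p_readout)
        gamma = np.zeros((self.n_spatial, self.n_spatial))
        for (p, q), op in self.rdm_ops.items():
            val = sum(c * means[s] for s, c in op.strings.items())
            gamma[p, q] = gamma[q, p] = float(val)
        return gamma

    def energy_sigma(self, shots: int) -> float:
        coeffs = [c for s, c in self.hamiltonian.strings.items() if s != (0, 0)]
        return propagate_error_bars(np.array(coeffs), shots)


@dataclass
class NoisySolvationReport:
    delta_solv_ev: float
    delta_solv_sigma_ev: float
    u_pol_ev: float
    u_pol_exact_ev: float
    delta_exact_ev: float
    trace_distance_gas: float
    trace_distance_solvated: float
    n_hamiltonian_strings: int
    n_rdm_strings: int
    energy_sigma_ha: float
    gas_history: list[float] = field(default_factory=list)
    solvated_history: list[float] = field(default_factory=list)


def noisy_solvation_experiment(
    config,
    noise_model: NoiseModel,
    shots: int = 8192,
    seed: int = 0,
    max_iter: int = 120,
    tail: int = 50,
) -> NoisySolvationReport:
    """Two independent noisy VQE runs (gas and solvated) and their difference.

    The solvation free energy is reported as the mean over the last ``tail``
    iterations of each run; the polarization-energy shortcut re-uses only the
    (trace-normalized) sampled 1-RDM of the gas run.
    """
    from scipy.optimize import minimize

    from .driver import build_problem, _run_variational
    from .vqe import VqeEngine

    rng = np.random.default_rng(seed)
    problem = build_problem(config)
    if problem.couplings is None:
        raise ValueError("noisy solvation experiment needs a solvent")
    integrals = problem.integrals
    ne = integrals.n_active_electrons

    # noiseless references (exact densities and converged energies)
    gas_exact = _run_variational(problem, config, solvated=False)
    solv_exact = _run_variational(problem, config, solvated=True)
    engine = VqeEngine(integrals)
    gamma_gas_exact = engine.rdms(gas_exact.ansatz, gas_exact.theta).gamma
    gamma_solv_exact = engine.rdms(solv_exact.ansatz, solv_exact.theta).gamma
    delta_exact = solvation_free_energy(solv_exact.energy, gas_exact.energy)

    obs = SampledObservables(integrals.n_act, integrals.h, integrals.g, integrals.e_offset)
    ansatz = gas_exact.ansatz
    cpl = problem.couplings

    def noisy_gamma(theta):
        rho = simulate_density(ansatz, theta, noise_model)
        return rho, obs.sampled_gamma(rho, shots, rng, noise_model.p_readout)

    def gas_cost(theta):
        rho = simulate_density(ansatz, theta, noise_model)
        return obs.sampled_energy(rho, shots, rng, noise_model.p_readout)

    def solvated_cost(theta):
        rho, gamma = noisy_gamma(theta)
        gamma = normalize_rdm_trace(gamma, ne)
        e = obs.sampled_energy(rho, shots, rng, noise_model.p_readout)
        v_tot = cpl.v_static + np.einsum("pq,pqi->i", gamma, cpl.K)
        return e + 0.5 * float(v_tot @ (cpl.Q @ v_tot))

    def run(cost):
        theta0 = rng.uniform(-0.1, 0.1, ansatz.n_parameters)
        history: list[float] = []
        minimize(lambda t: history.append(cost(t)) or history[-1], theta0,
                 method="COBYLA", options={"maxiter": max_iter, "rhobeg": 0.3})
        return history

    gas_hist = run(gas_cost)
    solv_hist = run(solvated_cost)
    gtail = np.array(gas_hist[-tail:])
    stail = np.array(solv_hist[-tail:])
    delta = (stail.mean() - gtail.mean()) * 27.211386
    delta_sigma = float(np.sqrt(stail.std() ** 2 + gtail.std() ** 2)) * 27.211386

    # polarization-energy shortcut: only the gas-run 1-RDM is measured
    theta_star = gas_exact.theta
    _, gamma_noisy = noisy_gamma(theta_star)
    gamma_noisy = normalize_rdm_trace(gamma_noisy, ne)
    u_pol_noisy = polarization_energy(gamma_noisy, integrals, cpl)
    u_pol_exact = polarization_energy(gamma_gas_exact, integrals, cpl)

    rho_solv = simulate_density(ansatz, solv_exact.theta, noise_model)
    gamma_solv_noisy = normalize_rdm_trace(
        obs.sampled_gamma(rho_solv, shots, rng, noise_model.p_readout), ne)

    return NoisySolvationReport(
        delta_solv_ev=float(delta),
        delta_solv_sigma_ev=delta_sigma,
        u_pol_ev=u_pol_noisy * 27.211386,
        u_pol_exact_ev=u_pol_exact * 27.211386,
        delta_exact_ev=delta_exact,
        trace_distance_gas=trace_distance_rdm(gamma_noisy, gamma_gas_exact, ne),
        trace_distance_solvated=trace_distance_rdm(gamma_solv_noisy, gamma_solv_exact, ne),
        n_hamiltonian_strings=obs.n_hamiltonian_strings(),
        n_rdm_strings=obs.n_rdm_strings(),
        energy_sigma_ha=obs.energy_sigma(shots),
        gas_history=gas_hist,
        solvated_history=solv_hist,
    )
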