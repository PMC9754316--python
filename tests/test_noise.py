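"""Shot sampling, noise channels, trace normalization and error propagation."""
import numpy as np
import pytest

from pcmvqe import RunConfig, SolventParams
from pcmvqe.fixtures import h3_plus
from pcmvqe.noise import (NoiseModel, SampledObservables, apply_noise,
                          noisy_solvation_experiment, normalize_rdm_trace,
                          propagate_error_bars, sample_pauli, simulate_density,
                          trace_distance_rdm)
from pcmvqe.qsim import Ansatz, Excitation, hf_state


def test_sample_pauli_eigenstate_is_exact():
    rng = np.random.default_rng(0)
    est = sample_pauli(hf_state(2, 0), "ZI", 17, rng)
    assert est.mean == 1.0
    est = sample_pauli(hf_state(2, 1), "ZI", 17, rng)   # qubit 0 occupied
    assert est.mean == -1.0
    assert est.sigma_bound == pytest.approx(1 / np.sqrt(17))


def test_sample_pauli_identity_and_errors():
    rng = np.random.default_rng(0)
    est = sample_pauli(hf_state(2, 1), "II", 5, rng)
    assert est.mean == 1.0 and est.sigma_bound == 0.0
    with pytest.raises(ValueError):
        sample_pauli(hf_state(2, 1), "ZI", 0, rng)
    with pytest.raises(ValueError):
        sample_pauli(hf_state(2, 1), "QI", 5, rng)


def test_sample_pauli_unbiased_x_on_zero():
    rng = np.random.default_rng(42)
    est = sample_pauli(hf_state(1, 0), "X", 10**5, rng)
    assert abs(est.mean) < 5 / np.sqrt(10**5)


def test_sample_pauli_unbiased_over_repeats():
    """Mean over seeded repeats lands within 4 sigma of the true expectation."""
    ansatz = Ansatz(2, 1, [Excitation("single", (0, 1))])
    psi = ansatz.prepare(np.array([0.8]))
    from pcmvqe.paulis import pauli_expectation

    truth = pauli_expectation(psi, 0b11, 0b00)  # XX
    shots, reps = 256, 200
    rng = np.random.default_rng(5)
    means = [sample_pauli(psi, "XX", shots, rng).mean for _ in range(reps)]
    sem = 1.0 / np.sqrt(shots * reps)
    assert np.mean(means) == pytest.approx(truth, abs=4 * sem)


def test_zero_noise_density_equals_pure_state():
    ansatz = Ansatz(4, 2, [Excitation("double", (0, 1, 2, 3))])
    theta = np.array([0.6])
    rho = apply_noise(ansatz, theta, NoiseModel())
    psi = ansatz.prepare(theta)
    np.testing.assert_allclose(rho, np.outer(psi, psi.conj()), atol=1e-12)


def test_full_depolarizing_gives_maximally_mixed_marginal():
    ansatz = Ansatz(2, 1, [Excitation("single", (0, 1))])
    rho = simulate_density(ansatz, np.array([0.3]), NoiseModel(p1=1.0))
    rng = np.random.default_rng(1)
    for pauli in ("XI", "YI", "ZI", "IX", "IZ"):
        est = sample_pauli(rho, pauli, 4096, rng)
        assert abs(est.mean) < 0.1


def test_noise_biases_energy_upward(h3p_solvation):
    """Depolarizing noise can only raise the variational cost above optimum."""
    gas = h3p_solvation.gas
    integrals = gas.problem.integrals
    obs = SampledObservables(integrals.n_act, integrals.h, integrals.g,
                             integrals.e_offset)
    rho_clean = simulate_density(gas.ansatz, gas.theta, None)
    e_clean = float(np.real(np.trace(
        _dense_h(obs) @ rho_clean)))
    rho_noisy = simulate_density(gas.ansatz, gas.theta,
                                 NoiseModel(p1=0.005, p2=0.02))
    e_noisy = float(np.real(np.trace(_dense_h(obs) @ rho_noisy)))
    assert e_clean == pytest.approx(gas.energy, abs=1e-8)
    assert e_noisy > e_clean + 1e-4


def _dense_h(obs: SampledObservables) -> np.ndarray:
    from pcmvqe.paulis import apply_pauli_string

    dim = 2**(2 * obs.n_spatial)
    eye = np.eye(dim, dtype=complex)
    H = np.zeros((dim, dim), dtype=complex)
    for (x, z), c in obs.hamiltonian.strings.items():
        H += c * np.array([apply_pauli_string(col, x, z) for col in eye]).T
    return H


def test_propagate_error_bars():
    assert propagate_error_bars([0.5], 8192) == pytest.approx(0.5 / np.sqrt(8192))
    assert propagate_error_bars([0.5], 8192) == pytest.approx(0.00553, abs=1e-5)
    c = [0.3, -0.2, 0.1]
    assert propagate_error_bars(c, 100) == pytest.approx(
        propagate_error_bars(list(reversed(c)), 100))
    assert propagate_error_bars(c, 10**12) < 1e-6
    with pytest.raises(ValueError):
        propagate_error_bars(c, 0)


def test_normalize_rdm_trace():
    g = np.diag([1.8, 0.1])
    out = normalize_rdm_trace(g, 2)
    np.testing.assert_allclose(out, g * (2 / 1.9))
    assert np.trace(out) == pytest.approx(2.0)
    np.testing.assert_allclose(normalize_rdm_trace(out, 2), out)  # idempotent
    # scaling only: eigenvectors untouched
    rng = np.random.default_rng(3)
    m = rng.normal(size=(3, 3))
    m = m @ m.T
    v1 = np.linalg.eigh(m)[1]
    v2 = np.linalg.eigh(normalize_rdm_trace(m, 4))[1]
    np.testing.assert_allclose(np.abs(v1), np.abs(v2), atol=1e-12)
    with pytest.raises(ValueError):
        normalize_rdm_trace(np.diag([-1.0, 0.0]), 2)


def test_trace_distance_properties():
    a, b = np.diag([2.0, 0.0]), np.diag([0.0, 2.0])
    assert trace_distance_rdm(a, a, 2) == 0.0
    assert trace_distance_rdm(a, b, 2) == pytest.approx(1.0)
    assert trace_distance_rdm(a, b, 2) == trace_distance_rdm(b, a, 2)
    with pytest.raises(ValueError):
        trace_distance_rdm(a, np.eye(3), 2)


def test_rdm_needs_fewer_strings_than_hamiltonian(h3p_solvation):
    integrals = h3p_solvation.gas.problem.integrals
    obs = SampledObservables(integrals.n_act, integrals.h, integrals.g,
                             integrals.e_offset)
    assert obs.n_rdm_strings() < obs.n_hamiltonian_strings()


@pytest.fixture(scope="module")
def noisy_cfg():
    return RunConfig(geometry=h3_plus(0.9857),
                     solvent=SolventParams(tess_level=1))


def test_trace_distance_decreases_with_noise(noisy_cfg, h3p_solvation):
    gas = h3p_solvation.gas
    integrals = gas.problem.integrals
    obs = SampledObservables(integrals.n_act, integrals.h, integrals.g,
                             integrals.e_offset)
    from pcmvqe.vqe import VqeEngine

    exact = VqeEngine(integrals).rdms(gas.ansatz, gas.theta).gamma
    dists = []
    rng = np.random.default_rng(11)
    for scale in (4.0, 1.0, 0.0):
        model = NoiseModel(p1=0.002 * scale, p2=0.02 * scale,
                           p_readout=0.01 * scale)
        rho = simulate_density(gas.ansatz, gas.theta, model)
        gamma = normalize_rdm_trace(obs.sampled_gamma(rho, 10**6, rng,
                                                      model.p_readout), 2)
        dists.append(trace_distance_rdm(gamma, exact, 2))
    assert dists[0] > dists[1] > dists[2]
    assert dists[2] < 0.01


def test_noisy_experiment_zero_noise_reduction(noisy_cfg):
    """With no channel noise and generous shots the noisy pipeline recovers
    the noiseless solvation free energy within optimizer scatter."""
    rep = noisy_solvation_experiment(noisy_cfg, NoiseModel(), shots=200000,
                                     seed=2, max_iter=80, tail=20)
    assert rep.delta_solv_ev == pytest.approx(rep.delta_exact_ev, abs=0.15)
    assert rep.u_pol_ev == pytest.approx(rep.u_pol_exact_ev, abs=0.05)


def test_upol_shortcut_beats_full_difference(noisy_cfg):
    """Ensemble property: the 1-RDM-only polarization-energy estimate is
    closer to its exact value than the two-run free-energy difference in the
    majority of seeded replicates."""
    model = NoiseModel(p1=0.002, p2=0.01, p_readout=0.02)
    wins = 0
    reps = 5
    for seed in range(reps):
        rep = noisy_solvation_experiment(noisy_cfg, model, shots=2048,
                                         seed=seed, max_iter=40, tail=15)
        err_upol = abs(rep.u_pol_ev - rep.u_pol_exact_ev)
        err_delta = abs(rep.delta_solv_ev - rep.delta_exact_ev)
        wins += err_upol <= err_delta
    assert wins > reps / 2
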