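"""The second-quantized solute-solvent coupling and free-energy functional."""
import numpy as np
import pytest

from pcmvqe import run_fci
from pcmvqe.constants import EV_PER_HARTREE
from pcmvqe.solvent_coupling import (Rdms, SolventCouplings, electronic_asc,
                                     free_energy, one_body_couplings,
                                     polarization_energy,
                                     solvation_free_energy, static_asc)

EPS_DMSO = 46.7


@pytest.fixture(scope="module")
def h3p(h3p_problem_dmso):
    prob = h3p_problem_dmso
    e, v, sec = run_fci(prob.integrals)
    return prob, sec.rdms(v), e


def test_static_asc_and_wnn_sign(h3p):
    prob, _, _ = h3p
    cpl = prob.couplings
    q, w_nn = static_asc(cpl.v_static, cpl.Q)
    np.testing.assert_allclose(q, cpl.q_static)
    assert w_nn < 0  # the response matrix is negative semidefinite
    assert static_asc(np.zeros_like(cpl.v_static), cpl.Q)[1] == 0.0


def test_couplings_j_equals_y_for_symmetric_response(h3p):
    prob, _, _ = h3p
    cpl = prob.couplings
    np.testing.assert_allclose(cpl.j, cpl.j.T, atol=1e-12)
    np.testing.assert_allclose(cpl.j, cpl.y, atol=1e-10)


def test_couplings_match_brute_force_tessera_loop(h3p):
    prob, _, _ = h3p
    cpl = prob.couplings
    n = prob.integrals.n_act
    j_loop = np.zeros((n, n))
    y_loop = np.zeros((n, n))
    qK = np.einsum("ij,pqj->pqi", cpl.Q, cpl.K)
    for p in range(n):
        for q in range(n):
            for i in range(len(cpl.v_static)):
                j_loop[p, q] += cpl.K[p, q, i] * cpl.q_static[i]
                y_loop[p, q] += cpl.v_static[i] * qK[p, q, i]
    np.testing.assert_allclose(cpl.j, j_loop, atol=1e-12)
    np.testing.assert_allclose(cpl.y, y_loop, atol=1e-12)


def test_electronic_asc_gauss_law(h3p):
    """Two active electrons induce +2 (eps-1)/eps of opposing surface charge."""
    prob, rdms, _ = h3p
    q_el = electronic_asc(rdms.gamma, prob.couplings.K, prob.couplings.Q)
    assert q_el.sum() == pytest.approx(2 * (EPS_DMSO - 1) / EPS_DMSO, rel=0.02)
    # linearity
    q2 = electronic_asc(2 * rdms.gamma, prob.couplings.K, prob.couplings.Q)
    np.testing.assert_allclose(q2, 2 * q_el, atol=1e-12)
    assert np.all(electronic_asc(0 * rdms.gamma, prob.couplings.K, prob.couplings.Q) == 0)


def test_free_energy_vacuum_reduction(h3p):
    prob, rdms, e_fci = h3p
    rep = free_energy(rdms, prob.integrals, None)
    assert rep.g_total == rep.e_gas == pytest.approx(e_fci, abs=1e-9)


def test_free_energy_internal_identity_and_upol_bound(h3p):
    prob, rdms, e_fci = h3p
    rep = free_energy(rdms, prob.integrals, prob.couplings)
    assert rep.g_total == pytest.approx(rep.e_gas + 0.5 * rep.u_int, abs=1e-12)
    u_pol = polarization_energy(rdms.gamma, prob.integrals, prob.couplings)
    assert u_pol <= 0
    assert rep.g_total == pytest.approx(e_fci + u_pol, abs=1e-10)
    # relaxation can only lower the functional below the frozen-density value
    g_sc, _, _ = run_fci(prob.integrals, pcm="self_consistent",
                         couplings=prob.couplings)
    assert g_sc <= rep.g_total + 1e-10
    delta = solvation_free_energy(g_sc, e_fci)
    assert delta <= u_pol * EV_PER_HARTREE + 1e-6


def test_free_energy_guards_bad_trace(h3p):
    prob, rdms, _ = h3p
    bad = Rdms(rdms.gamma * 1.01, rdms.Gamma)
    with pytest.raises(ValueError, match="trace"):
        free_energy(bad, prob.integrals, prob.couplings)
    free_energy(bad, prob.integrals, prob.couplings, check_trace=False)


def test_operator_vs_functional_bilinear_identity(h3p):
    """Contracting the one-body solvent operator with gamma reproduces the
    coupling pieces of the functional (operator/functional consistency)."""
    prob, rdms, _ = h3p
    cpl = prob.couplings
    rep = free_energy(rdms, prob.integrals, cpl)
    v_el = np.einsum("pq,pqi->i", rdms.gamma, cpl.K)
    # u_int = W_NN + 2 j.gamma + v_el Q v_el, assembled from the operator parts
    u_from_ops = rep.w_nn + 2 * np.einsum("pq,pq->", cpl.j, rdms.gamma) \
        + float(v_el @ (cpl.Q @ v_el))
    assert rep.u_int == pytest.approx(u_from_ops, abs=1e-12)
    assert rep.e_static_coupling == pytest.approx(
        2 * np.einsum("pq,pq->", cpl.j, rdms.gamma), abs=1e-12)


def test_epsilon_monotonicity_of_free_energy(h3p_geometry):
    """For a fixed density, G is non-increasing in the dielectric constant."""
    from pcmvqe import RunConfig, SolventParams, build_problem

    gs = []
    rdms = None
    for eps in (1.0, 2.0, 10.0, 46.7, 78.39):
        prob = build_problem(RunConfig(
            geometry=h3p_geometry,
            solvent=SolventParams(epsilon=eps, tess_level=1)))
        if rdms is None:
            _, v, sec = run_fci(prob.integrals)
            rdms = sec.rdms(v)
        gs.append(free_energy(rdms, prob.integrals, prob.couplings).g_total)
    assert np.all(np.diff(gs) <= 1e-12)


def test_solvation_free_energy_conversion():
    assert solvation_free_energy(-1.4231, -1.2744) == pytest.approx(-4.046, abs=5e-4)
    assert solvation_free_energy(-1.0, -1.0) == 0.0
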