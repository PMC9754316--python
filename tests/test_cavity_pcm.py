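"""Cavity tessellation and IEF-PCM operator properties: Gauss's law, the
Born sphere, the closed-surface sum rule, and response-matrix definiteness."""
import numpy as np
import pytest

from pcmvqe.cavity import SolventParams, build_cavity
from pcmvqe.constants import BOHR_PER_ANGSTROM
from pcmvqe.geometry import Geometry
from pcmvqe.pcm import apply_response, build_SDA, response_matrix

EPS_DMSO = 46.7
EPS_WATER = 78.39


def _lone_sphere(level, epsilon=EPS_WATER):
    g = Geometry(["H"], [[0.0, 0.0, 0.0]], net_charge=1)
    params = SolventParams(epsilon=epsilon, tess_level=level)
    cav = build_cavity(g, params)
    return cav, cav.sphere_radii[0]


def test_single_sphere_area_and_normals():
    cav, R = _lone_sphere(2)
    assert cav.areas.sum() == pytest.approx(4 * np.pi * R**2, rel=0.005)
    np.testing.assert_allclose(np.linalg.norm(cav.normals, axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(np.linalg.norm(cav.centers, axis=1), R, atol=1e-10)


def test_disjoint_spheres_keep_full_area():
    g = Geometry(["H", "H"], [[0, 0, 0], [0, 0, 8.0]])
    cav = build_cavity(g, SolventParams(tess_level=2))
    R = cav.sphere_radii[0]
    assert cav.areas.sum() == pytest.approx(2 * 4 * np.pi * R**2, rel=0.005)


def test_overlapping_spheres_bury_surface():
    g = Geometry(["H", "H"], [[0, 0, 0], [0, 0, 0.9]])
    cav = build_cavity(g, SolventParams(tess_level=2))
    R = cav.sphere_radii[0]
    assert cav.areas.sum() < 2 * 4 * np.pi * R**2 * 0.95
    # normals still point away from the owning sphere centers
    for i in range(cav.n_tesserae):
        own = cav.sphere_centers[cav.sphere_of[i]]
        assert (cav.centers[i] - own) @ cav.normals[i] > 0
    # exposed-surface invariant: centers outside every foreign sphere
    for j in range(2):
        foreign = cav.sphere_of != j
        d = np.linalg.norm(cav.centers[foreign] - cav.sphere_centers[j], axis=1)
        assert np.all(d >= cav.sphere_radii[j] - 1e-12)


def test_double_layer_sum_rule():
    cav, _ = _lone_sphere(3)
    S, D, A = build_SDA(cav)
    a = np.diag(A)
    np.testing.assert_allclose(D @ a, -2 * np.pi * np.ones(len(a)), atol=1e-10)
    # before the diagonal fix the off-diagonal sum already approaches -2 pi
    off = D - np.diag(np.diag(D))
    assert np.abs((off @ a) + 2 * np.pi).max() < 0.05 * 2 * np.pi


def test_single_layer_positive_definite():
    for level in (1, 2):
        cav, _ = _lone_sphere(level)
        S, _, _ = build_SDA(cav)
        assert np.linalg.eigvalsh(S).min() > 0


def test_vacuum_limit_zero_response():
    cav, _ = _lone_sphere(2)
    S, D, A = build_SDA(cav)
    assert np.all(response_matrix(S, D, A, 1.0) == 0.0)
    Q_close = response_matrix(S, D, A, 1.0 + 1e-6)
    assert np.abs(Q_close).max() < 1e-6


def test_response_negative_semidefinite():
    cav, _ = _lone_sphere(2, EPS_DMSO)
    S, D, A = build_SDA(cav)
    Q = response_matrix(S, D, A, EPS_DMSO)
    np.testing.assert_allclose(Q, Q.T, atol=0)
    assert np.linalg.eigvalsh(Q).max() <= 1e-10


@pytest.mark.parametrize("level", [1, 2, 3])
def test_born_sphere_gauss_law_and_energy(level):
    cav, R = _lone_sphere(level)
    S, D, A = build_SDA(cav)
    Q = response_matrix(S, D, A, EPS_WATER)
    V = 1.0 / np.linalg.norm(cav.centers, axis=1)
    q = apply_response(Q, V)
    assert q.sum() == pytest.approx(-(EPS_WATER - 1) / EPS_WATER, rel=0.01)
    born = -(1 - 1 / EPS_WATER) / (2 * R)
    assert 0.5 * V @ q == pytest.approx(born, rel=0.02)


def test_born_error_does_not_grow_with_refinement():
    errs = []
    for level in (1, 2, 3):
        cav, R = _lone_sphere(level)
        S, D, A = build_SDA(cav)
        Q = response_matrix(S, D, A, EPS_WATER)
        V = 1.0 / np.linalg.norm(cav.centers, axis=1)
        born = -(1 - 1 / EPS_WATER) / (2 * R)
        errs.append(abs(0.5 * V @ Q @ V - born) / abs(born))
    assert errs[2] <= errs[0] + 1e-3
    assert max(errs) < 0.02


def test_conductor_limit_total_charge():
    cav, R = _lone_sphere(2, epsilon=1e6)
    S, D, A = build_SDA(cav)
    Q = response_matrix(S, D, A, 1e6)
    V = 1.0 / np.linalg.norm(cav.centers, axis=1)
    assert (Q @ V).sum() == pytest.approx(-1.0, rel=0.01)


def test_apply_response_linearity_and_shapes():
    cav, _ = _lone_sphere(1)
    S, D, A = build_SDA(cav)
    Q = response_matrix(S, D, A, EPS_DMSO)
    V = np.linspace(0.1, 1.0, cav.n_tesserae)
    np.testing.assert_allclose(apply_response(Q, 2 * V), 2 * apply_response(Q, V))
    assert np.all(apply_response(Q, np.zeros(cav.n_tesserae)) == 0)
    with pytest.raises(ValueError):
        apply_response(Q, V[:-1])


def test_h3p_gauss_law_nuclear_potential(h3p_problem_dmso):
    """Enclosed +3 nuclear charge induces -3 (eps-1)/eps on the surface."""
    from pcmvqe.geometry import nuclear_potential

    prob = h3p_problem_dmso
    v_n = nuclear_potential(prob.geometry, prob.cavity.centers)
    assert np.all(v_n > 0)
    q = prob.couplings.Q @ v_n
    expected = -3 * (EPS_DMSO - 1) / EPS_DMSO
    assert q.sum() == pytest.approx(expected, rel=0.02)
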