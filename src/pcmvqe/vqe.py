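"""Variational optimization of excitation circuits against gas-phase and
solvated cost functionals.

The cost engine evaluates energies in the fixed particle-number sector of the
register (where the circuit provably stays), which makes a single evaluation
a handful of small sparse matrix-vector products.  Gradients are exact
statevector derivatives assembled by an adjoint sweep over the circuit; for
the solvated functional the density-dependent term is quadratic in the 1-RDM,
so the exact gradient is the expectation of an effective Hamiltonian that
includes the instantaneous reaction field.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .active_space import ActiveSpaceIntegrals
from .fci import SectorOperators
from .qsim import Ansatz, Excitation, apply_excitation, apply_excitation_derivative
from .solvent_coupling import SolventCouplings


@dataclass
class OptimizerSettings:
    name: str = "adaptive_gd"       # adaptive_gd | lbfgs | cobyla
    max_iter: int = 20000
    tol: float = 1e-8               # stop when an accepted step changes the cost less
    initial_step: float = 0.25
    fd_step: float = 1e-4           # central-difference step when no gradient is given
    seed: int | None = None


class VqeEngine:
    """Shared machinery for cost, exact gradient and RDMs of an ansatz state."""

    def __init__(self, integrals: ActiveSpaceIntegrals,
                 couplings: SolventCouplings | None = None):
        self.integrals = integrals
        self.couplings = couplings
        n_e = integrals.n_active_electrons
        self.n_qubits = 2 * integrals.n_act
        self.n_electrons = n_e
        self.sector = SectorOperators(integrals.n_act, (n_e + 1) // 2, n_e // 2)
        self.h_eff1 = integrals.h - 0.5 * np.einsum("prrq->pq", integrals.g)

    # -- state preparation -------------------------------------------------
    def prepare(self, ansatz: Ansatz, theta: np.ndarray) -> np.ndarray:
        return np.real(ansatz.prepare(theta)).astype(float)

    def _sector_vec(self, state: np.ndarray) -> np.ndarray:
        return state[self.sector.dets]

    # -- energy pieces -----------------------------------------------------
    def _terms(self, v: np.ndarray):
        W = self.sector.excitation_stack(v)
        gamma = np.einsum("pqd,d->pq", W, v)
        B = np.einsum("pqrs,rsd->pqd", self.integrals.g, W, optimize=True)
        e_gas = (
            self.integrals.e_offset
            + float(np.einsum("pq,pq->", self.h_eff1, gamma))
            + 0.5 * float(np.einsum("qpd,pqd->", W, B))
        )
        return e_gas, gamma, W, B

    def cost_terms(self, state: np.ndarray):
        """(cost, e_gas, gamma, reaction-field coupling c_pq or None)."""
        v = self._sector_vec(state)
        e_gas, gamma, W, B = self._terms(v)
        if self.couplings is None:
            return e_gas, e_gas, gamma, None, (v, W, B)
        V = self.couplings.v_static + np.einsum("pq,pqi->i", gamma, self.couplings.K)
        q = self.couplings.Q @ V
        c = np.einsum("pqi,i->pq", self.couplings.K, q)
        cost = e_gas + 0.5 * float(V @ q)
        return cost, e_gas, gamma, c, (v, W, B)

    def cost(self, ansatz: Ansatz, theta: np.ndarray) -> float:
        return self.cost_terms(self.prepare(ansatz, theta))[0]

    # -- exact gradient (adjoint sweep) -------------------------------------
    def cost_and_grad(self, ansatz: Ansatz, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        # forward pass with cached intermediates
        from .qsim import hf_state

        psi = np.real(hf_state(self.n_qubits, self.n_electrons))
        states = [psi]
        for exc, t in zip(ansatz.excitations, theta):
            psi = apply_excitation(psi, exc, float(t))
            states.append(psi)
        cost, e_gas, gamma, c, (v, W, B) = self.cost_terms(states[-1])

        # lambda = H_eff |psi> in the sector, lifted back to the register
        h1 = self.h_eff1 if c is None else self.h_eff1 + c
        Hv = self.integrals.e_offset * v + np.einsum("pq,pqd->d", h1, W)
        for p in range(self.integrals.n_act):
            for q in range(self.integrals.n_act):
                Hv += 0.5 * (self.sector.e_pq[p][q] @ B[p, q])
        lam = np.zeros_like(states[-1])
        lam[self.sector.dets] = Hv

        grad = np.empty(len(theta))
        b = lam
        for k in range(len(theta) - 1, -1, -1):
            exc, t = ansatz.excitations[k], float(theta[k])
            dpsi = apply_excitation_derivative(states[k], exc, t)
            grad[k] = 2.0 * float(np.dot(b, dpsi))
            b = apply_excitation(b, exc, -t)
        return cost, grad

    def rdms(self, ansatz: Ansatz, theta: np.ndarray):
        from .qsim import measure_rdms

        state = ansatz.prepare(theta)
        return measure_rdms(state, self.integrals.n_act)


# ---------------------------------------------------------------------------
# Candidate pools and adaptive gate selection
# ---------------------------------------------------------------------------

def candidate_doubles(n_qubits: int, n_electrons: int) -> list[Excitation]:
    """All Sz-conserving double excitations from the Hartree-Fock reference."""
    occ = range(n_electrons)
    virt = range(n_electrons, n_qubits)
    pool = []
    for i in occ:
        for j in occ:
            if j <= i:
                continue
            for a in virt:
                for b in virt:
                    if b <= a:
                        continue
                    if (i % 2 + j % 2) == (a % 2 + b % 2):
                        pool.append(Excitation("double", (i, j, a, b)))
    return pool


def candidate_singles(n_qubits: int, n_electrons: int) -> list[Excitation]:
    """Spin-preserving single excitations from the Hartree-Fock reference."""
    return [
        Excitation("single", (i, a))
        for i in range(n_electrons)
        for a in range(n_electrons, n_qubits)
        if i % 2 == a % 2
    ]


def adaptive_select(
    engine: VqeEngine,
    threshold: float = 1e-5,
    settings: OptimizerSettings | None = None,
) -> tuple[Ansatz, np.ndarray]:
    """Gradient-screened circuit construction.

    Phase 1 screens all Sz-conserving doubles at theta = 0 on the HF state;
    phase 2 optimizes the retained doubles; phase 3 screens singles at the
    optimized point.  Returns the ordered ansatz and a starting parameter
    vector (optimized doubles, zeros for the singles).
    """
    settings = settings or OptimizerSettings()
    nq, ne = engine.n_qubits, engine.n_electrons
    doubles_pool = candidate_doubles(nq, ne)
    singles_pool = candidate_singles(nq, ne)
    if not doubles_pool and not singles_pool:
        raise ValueError("empty excitation pool")

    retained: list[Excitation] = []
    for exc in doubles_pool:
        probe = Ansatz(nq, ne, [exc])
        _, g = engine.cost_and_grad(probe, np.zeros(1))
        if abs(g[0]) > threshold:
            retained.append(exc)

    theta = np.zeros(len(retained))
    if retained:
        # converge the doubles tightly: the singles screen reads gradients at
        # this point, so leftover phase-2 residue must sit below any threshold
        ansatz = Ansatz(nq, ne, list(retained))
        phase2 = replace(settings, tol=min(settings.tol, 1e-13))
        theta, _ = optimize(
            lambda t: engine.cost(ansatz, t), theta, phase2,
            grad_fn=lambda t: engine.cost_and_grad(ansatz, t)[1],
        )

    kept_singles: list[Excitation] = []
    for exc in singles_pool:
        probe = Ansatz(nq, ne, retained + [exc])
        _, g = engine.cost_and_grad(probe, np.append(theta, 0.0))
        if abs(g[-1]) > threshold:
            kept_singles.append(exc)

    full = Ansatz(nq, ne, retained + kept_singles)
    return full, np.append(theta, np.zeros(len(kept_singles)))


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

@dataclass
class OptimizationHistory:
    iterations: list[int] = field(default_factory=list)
    costs: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)
    converged: bool = False

    def append(self, cost: float, grad_norm: float = np.nan) -> None:
        self.iterations.append(len(self.iterations))
        self.costs.append(float(cost))
        self.grad_norms.append(float(grad_norm))


def _fd_gradient(cost_fn, theta: np.ndarray, h: float) -> np.ndarray:
    grad = np.empty_like(theta)
    for k in range(len(theta)):
        e = np.zeros_like(theta)
        e[k] = h
        grad[k] = (cost_fn(theta + e) - cost_fn(theta - e)) / (2 * h)
    return grad


def optimize(
    cost_fn,
    theta0: np.ndarray,
    settings: OptimizerSettings | None = None,
    grad_fn=None,
) -> tuple[np.ndarray, OptimizationHistory]:
    """Minimize a scalar cost over circuit parameters.

    ``adaptive_gd`` (noiseless default) is a monotone gradient descent with
    an adaptive step: accepted steps never increase the cost, the step grows
    on success and backtracks on failure; it stops when an accepted step
    improves the cost by less than ``tol``.  ``cobyla`` is the derivative-free
    path for noisy cost functions; ``lbfgs`` wraps scipy's L-BFGS-B.
    """
    settings = settings or OptimizerSettings()
    theta = np.asarray(theta0, dtype=float).copy()
    history = OptimizationHistory()
    if theta.size == 0:
        history.append(cost_fn(theta))
        history.converged = True
        return theta, history

    if settings.name == "cobyla":
        def record(t):
            history.append(cost_fn(np.asarray(t)))
        res = minimize(cost_fn, theta, method="COBYLA", callback=record,
                       options={"maxiter": settings.max_iter, "rhobeg": 0.3,
                                "tol": settings.tol})
        history.converged = bool(res.success)
        return np.asarray(res.x), history

    if settings.name == "lbfgs":
        jac = grad_fn if grad_fn is not None else (
            lambda t: _fd_gradient(cost_fn, t, settings.fd_step))
        def record(t):
            history.append(cost_fn(np.asarray(t)))
        res = minimize(cost_fn, theta, jac=jac, method="L-BFGS-B", callback=record,
                       options={"maxiter": settings.max_iter, "ftol": settings.tol,
                                "gtol": 1e-10})
        history.converged = bool(res.success)
        return np.asarray(res.x), history

    if settings.name != "adaptive_gd":
        raise ValueError(f"unknown optimizer {settings.name!r}")

    gradient = grad_fn if grad_fn is not None else (
        lambda t: _fd_gradient(cost_fn, t, settings.fd_step))
    f = cost_fn(theta)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite cost at the starting point")
    step = settings.initial_step
    history.append(f)
    for _ in range(settings.max_iter):
        g = gradient(theta)
        gnorm = float(np.linalg.norm(g))
        if gnorm < 1e-9:
            history.converged = True
            break
        accepted = False
        while step > 1e-13:
            trial = theta - step * g
            ft = cost_fn(trial)
            if not np.isfinite(ft):
                raise FloatingPointError("non-finite cost during line search")
            if ft <= f:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            history.converged = True  # no descent possible at machine resolution
            break
        improvement = f - ft
        theta, f = trial, ft
        step *= 1.6
        history.append(f, gnorm)
        if improvement < settings.tol and gnorm < 1e-4:
            history.converged = True
            break
    return theta, history
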