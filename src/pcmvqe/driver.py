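"""End-to-end workflows: gas VQE, self-consistent PCM-VQE, FCI references,
internal geometry optimization and dissociation scans.

The solvated loop follows the five-step scheme: prepare the trial state,
measure the reduced density matrices, update the apparent surface charges and
coupling matrices, evaluate the free-energy functional and its gradient, and
take an optimizer step; the solvent response matrix is built once and reused
throughout.  With the exact-gradient engine every optimizer iteration is one
such cycle.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .active_space import ActiveSpaceIntegrals, active_space_transform
from .basis import build_basis
from .cavity import Cavity, SolventParams, build_cavity
from .constants import EV_PER_HARTREE
from .fci import run_fci
from .fixtures import Fixture, get_fixture
from .geometry import Geometry, parse_xyz
from .integrals import core_integrals, electronic_potential_integrals
from .pcm import build_SDA, response_matrix
from .qsim import Ansatz
from .scf import run_hf
from .solvent_coupling import (FreeEnergyReport, SolventCouplings, free_energy,
                               polarization_energy, solvation_free_energy)
from .vqe import OptimizerSettings, VqeEngine, adaptive_select, optimize


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    geometry: Geometry | str            # a Geometry, fixture name, or XYZ text
    frozen_orbitals: int | None = None  # None: fixture recommendation (or 0)
    active_orbitals: int | None = None
    solvent: SolventParams | None = None
    ansatz_threshold: float = 1e-5
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    outer_tol: float = 1e-8
    seed: int = 0
    optimize_geometry: bool = False     # optimize fixture template at FCI first

    def resolve_geometry(self) -> tuple[Geometry, int]:
        """Return the geometry and the frozen-orbital count."""
        if isinstance(self.geometry, Geometry):
            geom, frozen_default = self.geometry, 0
        elif "\n" in self.geometry:
            geom, frozen_default = parse_xyz(self.geometry), 0
        else:
            fix = get_fixture(self.geometry)
            geom = (optimize_geometry(fix) if self.optimize_geometry
                    else fix.template(*fix.x0))
            frozen_default = fix.frozen_orbitals
        frozen = self.frozen_orbitals if self.frozen_orbitals is not None else frozen_default
        return geom, frozen


@dataclass
class Problem:
    """Assembled integrals and (optional) solvent operators for one geometry."""

    geometry: Geometry
    integrals: ActiveSpaceIntegrals
    couplings: SolventCouplings | None
    cavity: Cavity | None
    scf_energy: float
    solvent: SolventParams | None


def build_problem(config: RunConfig) -> Problem:
    geom, frozen = config.resolve_geometry()
    basis = build_basis(geom)
    core = core_integrals(basis, geom)
    scf = run_hf(core, geom.n_electrons)
    cavity = couplings = None
    K_ao = points = None
    if config.solvent is not None:
        cavity = build_cavity(geom, config.solvent)
        points = cavity.centers
        K_ao = electronic_potential_integrals(basis, points)
    integrals = active_space_transform(
        core, scf, geom.n_electrons, frozen_orbitals=frozen,
        active_orbitals=config.active_orbitals,
        K_ao=K_ao, geometry=geom, tessera_points=points,
    )
    if config.solvent is not None:
        S, D, A = build_SDA(cavity)
        Q = response_matrix(S, D, A, config.solvent.epsilon)
        couplings = SolventCouplings(Q, integrals.K, integrals.v_static)
    return Problem(geom, integrals, couplings, cavity, scf.e_total, config.solvent)


@dataclass
class RunResult:
    report: FreeEnergyReport
    theta: np.ndarray
    ansatz: Ansatz
    history_costs: list[float]
    converged: bool
    problem: Problem

    @property
    def energy(self) -> float:
        return self.report.g_total

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": range(len(self.history_costs)),
                             "cost": self.history_costs})


def _run_variational(problem: Problem, config: RunConfig, solvated: bool) -> RunResult:
    gas_engine = VqeEngine(problem.integrals, couplings=None)
    ansatz, theta_warm = adaptive_select(
        gas_engine, threshold=config.ansatz_threshold, settings=config.optimizer)
    engine = (VqeEngine(problem.integrals, problem.couplings)
              if solvated else gas_engine)
    settings = replace(config.optimizer, tol=config.outer_tol)
    theta0 = np.zeros(ansatz.n_parameters)
    theta, history = optimize(
        lambda t: engine.cost(ansatz, t), theta0, settings,
        grad_fn=lambda t: engine.cost_and_grad(ansatz, t)[1],
    )
    rdms = engine.rdms(ansatz, theta)
    report = free_energy(rdms, problem.integrals,
                         problem.couplings if solvated else None)
    return RunResult(report, theta, ansatz, history.costs, history.converged, problem)


def run_vqe_gas(config: RunConfig) -> RunResult:
    """Adaptive-ansatz VQE for the gas-phase ground state."""
    config = replace(config, solvent=None) if config.solvent is not None else config
    return _run_variational(build_problem(config), config, solvated=False)


def run_pcm_vqe(config: RunConfig) -> RunResult:
    """Self-consistent PCM-VQE minimization of the free energy in solution."""
    if config.solvent is None:
        raise ValueError("run_pcm_vqe needs a solvent; use run_vqe_gas otherwise")
    return _run_variational(build_problem(config), config, solvated=True)


@dataclass
class SolvationResult:
    gas: RunResult
    solvated: RunResult
    u_pol: float               # Hartree, from the gas-optimal density
    delta_solv_ev: float

    @property
    def delta_solv_hartree(self) -> float:
        return self.solvated.energy - self.gas.energy


def run_solvation(config: RunConfig) -> SolvationResult:
    """Gas VQE + PCM-VQE on the same geometry; reports Delta G_solv."""
    if config.solvent is None:
        raise ValueError("run_solvation needs a solvent")
    problem = build_problem(config)
    gas = _run_variational(problem, config, solvated=False)
    solv = _run_variational(problem, config, solvated=True)
    gamma_gas = VqeEngine(problem.integrals).rdms(gas.ansatz, gas.theta).gamma
    u_pol = polarization_energy(gamma_gas, problem.integrals, problem.couplings)
    delta = solvation_free_energy(solv.energy, gas.energy)
    solv.report.delta_solv_ev = delta
    return SolvationResult(gas, solv, u_pol, delta)


def optimize_geometry(fixture: Fixture | str, method: str = "fci",
                      xatol: float = 1e-5) -> Geometry:
    """Optimize a fixture's template parameters against gas-phase FCI (or HF)."""
    if isinstance(fixture, str):
        fixture = get_fixture(fixture)

    def energy(params) -> float:
        geom = fixture.template(*np.atleast_1d(params))
        basis = build_basis(geom)
        core = core_integrals(basis, geom)
        scf = run_hf(core, geom.n_electrons)
        if method == "hf":
            return scf.e_total
        integrals = active_space_transform(core, scf, geom.n_electrons)
        return run_fci(integrals)[0]

    if len(fixture.x0) == 1:
        res = minimize_scalar(lambda x: energy([x]), bounds=fixture.bounds[0],
                              method="bounded", options={"xatol": xatol})
        params = [res.x]
    else:
        res = minimize(energy, x0=list(fixture.x0), method="Nelder-Mead",
                       options={"xatol": xatol, "fatol": 1e-10})
        params = list(res.x)
    for p, (lo, hi) in zip(params, fixture.bounds):
        if abs(p - lo) < 10 * xatol or abs(p - hi) < 10 * xatol:
            warnings.warn(f"{fixture.name}: optimum at template bound ({p:.4f})")
    return fixture.template(*params)


@dataclass
class ScanResult:
    table: pd.DataFrame          # r, e_gas, g, u_pol_ev, delta_solv_ev
    failures: list[tuple[float, str]]

    def argmin_u_pol(self) -> float:
        return float(self.table.r[self.table.u_pol_ev.idxmin()])


def scan_double_dissociation(
    r_grid: np.ndarray,
    fixed_angle: float,
    solvent: SolventParams | None = None,
    method: str = "fci",
    config: RunConfig | None = None,
) -> ScanResult:
    """Symmetric O-H double-stretch scan of water.

    At each grid point: gas ground state and its polarization energy (the
    frozen-density solvent interaction), plus the self-consistently relaxed
    free energy in solution.  ``method`` selects exact diagonalization
    (``"fci"``) or the adaptive variational circuit (``"vqe"``, with an
    iteration budget that grows with the bond distance).
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be strictly increasing")
    solvent = solvent or SolventParams(epsilon=78.39)
    base = config or RunConfig(geometry="h2o")
    fix = get_fixture("h2o")
    rows, failures = [], []
    for i, r in enumerate(r_grid):
        geom = fix.template(float(r), fixed_angle)
        cfg = replace(base, geometry=geom, frozen_orbitals=fix.frozen_orbitals,
                      solvent=solvent)
        if method == "vqe":
            budget = int(min(500, 150 + 350 * (r - r_grid[0]) / max(r_grid[-1] - r_grid[0], 1e-9)))
            cfg = replace(cfg, optimizer=replace(cfg.optimizer, max_iter=budget * 50))
        try:
            problem = build_problem(cfg)
            if method == "fci":
                e_gas, v_gas, sec = run_fci(problem.integrals)
                gamma_gas = sec.gamma(v_gas)
                g_solv, _, _ = run_fci(problem.integrals, pcm="self_consistent",
                                       couplings=problem.couplings)
            else:
                gas = _run_variational(problem, cfg, solvated=False)
                solv = _run_variational(problem, cfg, solvated=True)
                e_gas, g_solv = gas.energy, solv.energy
                gamma_gas = VqeEngine(problem.integrals).rdms(gas.ansatz, gas.theta).gamma
            u_pol = polarization_energy(gamma_gas, problem.integrals, problem.couplings)
            rows.append({"r": r, "e_gas": e_gas, "g": g_solv,
                         "u_pol_ev": u_pol * EV_PER_HARTREE,
                         "delta_solv_ev": (g_solv - e_gas) * EV_PER_HARTREE})
        except Exception as exc:  # per-point failures recorded, scan continues
            failures.append((float(r), str(exc)))
    return ScanResult(pd.DataFrame(rows), failures)
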