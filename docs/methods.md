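# Methods

## Model

A solute molecule sits in a molecular-shaped cavity inside a structureless
polarizable dielectric of constant `eps`.  Its charge density induces
apparent surface charges (ASC) on the cavity boundary; the ASC react back on
the solute.  In the integral-equation formalism of the polarizable continuum
model the ASC are a linear response to the molecular electrostatic potential
(MEP) on the surface, and after discretizing the surface into tesserae the
response is a single matrix `Q` acting on the MEP vector `V`:

    q = Q V,   Q = -[2 pi f_eps I - D A]^-1 (2 pi I - D A) S^-1

with `S_ij = 1/|s_i - s_j|` (single layer), `D_ij = n_j.(s_i - s_j)/|s_i -
s_j|^3` (double layer, normal-derivative kernel), `A = diag(a_i)` the
tessera areas, and `f_eps = (eps+1)/(eps-1)`.  Diagonal elements use the
canonical collocation choices `S_ii = 1.0694 sqrt(4 pi / a_i)` and the
closed-surface sum rule `sum_j D_ij a_j = -2 pi`, which fixes `D_ii`.  `Q`
is symmetrized, `Q <- (Q + Q^T)/2`; this makes the free energy an exact
quadratic form and the nuclear->electronic and electronic->nuclear coupling
matrices identical (`j = y`), at no measurable cost in accuracy (the Born
sphere is reproduced to ~1e-4 relative).  `Q` is negative semidefinite, so
polarization never destabilizes.

The electronic problem is formulated in second quantization over an active
space of molecular orbitals.  With spatial 1- and 2-RDMs `gamma_pq = <E_pq>`
and `Gamma_pqrs = <E_pq E_rs - d_qr E_ps>` (chemists' index pairing, like
the two-electron integrals `(pq|rs)`), the cost functional is

    G = E_off + sum h_pq gamma_pq + 1/2 sum g_pqrs Gamma_pqrs
        + 1/2 V_tot^T Q V_tot,
    V_tot,i = v_static,i + sum_pq gamma_pq K_pq,i

where `K_pq,i = -int chi_p chi_q / |r - s_i|` is the potential of the
elementary electronic density at tessera `i` and `v_static` collects the
nuclear *and frozen-core* potential.  Folding the frozen-core density into
the static potential is required for the functional to reduce exactly to the
gas-phase energy at `eps = 1` with a frozen core; the partial trace identity
`sum_r Gamma_pqrr = (N-1) gamma_pq` holds in this pairing convention.

The `1/2` polarization-work prefactor is pinned by an internal consistency
requirement: the difference between the solvated and gas energies of a run,
converted at 27.211386 eV/Ha, must equal the reported solvation free energy;
this is asserted in the tests.

## Electronic-structure stack

* **Integrals.**  Contracted s/p Gaussians (bundled STO-3G tables for H-O),
  evaluated by McMurchie-Davidson Hermite expansions with Boys functions
  (`hyp1f1`).  The engine is validated element-by-element against published
  H2/STO-3G matrix elements at R = 1.4 bohr and against a 3-D quadrature
  oracle for the tessera-potential integrals.  Chemists' `(pq|rs)` ordering
  throughout.
* **SCF.**  DIIS-free damped Roothaan with automatic fallback to heavier
  damping plus a virtual-orbital level shift for stretched geometries;
  convergence 1e-10 on energy and 1e-8 on the Fock-density commutator.
* **Active space.**  Lowest occupied MOs may be frozen; their mean field is
  folded into `h` and the scalar offset, their density into `v_static`.
  Gas-phase HF orbitals are the default one-electron basis for solvated
  runs (naively replacing gas integrals with "in-solution" integrals does
  not minimize the free-energy functional; the basis choice is exposed via
  the SCF's optional PCM coupling rather than hidden).
* **FCI.**  Determinant CI in the fixed (N_alpha, N_beta) sector, encoded
  with the same interleaved spin-orbital bitmasks as the qubit register.
  The Hamiltonian is applied matrix-free through cached sparse
  singlet-excitation matrices (about 2 n^2 sparse matvecs per application);
  `eigsh` on a LinearOperator, dense diagonalization below dimension 64.
  The FCI oracle also provides the rigid (frozen-density) and
  self-consistent PCM references.

## Cavity

Union of scaled van der Waals spheres; each sphere is tessellated by
recursive icosahedral subdivision (20 * 4^level triangles, level 3 = 1280 by
default), tessera centers are centroid projections, areas are exact
spherical-triangle areas.  Tesserae whose center falls strictly inside
another sphere are discarded; tesserae cut by a neighbouring sphere keep the
exposed fraction of their area (estimated from seven sample points per
triangle).  This replaces the GePol construction (cut tesserae, added
spheres) with a simpler convergent scheme; single-sphere areas are exact to
numerical precision and the Born solvation energy converges to ~0.01%.

**Radii.**  Default: UFF van der Waals radii, unscaled (H 1.443, Be 1.3725,
O 1.75 angstrom).  The hydrogen sphere - numerically identical to the
scaled-Bondi 1.44 A sphere - was fixed by calibrating against the
trihydrogen-cation solvation benchmark, after which no other radius was
adjusted; UFF was preferred over Bondi because it covers beryllium natively
and its single scale factor (1.0) then reproduces the neutral-solute
benchmarks without further tuning.  Every report records the radii actually
used.  Dielectric defaults: DMSO 46.7, water 78.39.

## Quantum simulation

Qubit `k` holds spin-orbital `k`, interleaved alpha/beta; the Hartree-Fock
reference occupies the first `N_e` qubits.  Excitation gates are Givens
rotations on the two- or four-qubit occupation subspace; interior
Jordan-Wigner parities are not applied inside a gate (the variational
freedom absorbs the resulting sign conventions), while RDM *measurement*
uses full Jordan-Wigner parity strings, so every measured quantity is
exactly fermionic - the equivalence with the fermionic matrix exponential is
asserted for adjacent wires, and the measured energy is checked against a
dense Pauli-resolved Hamiltonian to 1e-10.

**Adaptive ansatz.**  Phase 1 screens all Sz-conserving double excitations
from the HF state by the magnitude of their cost gradient at theta = 0
(threshold 1e-5 Ha/rad by default); phase 2 optimizes the retained doubles
tightly (so that screening residue stays below any sensible threshold);
phase 3 screens spin-preserving singles at that optimized point.  For the
trihydrogen cation this yields exactly the two paired double excitations
over thresholds 1e-8..1e-3; for beryllium hydride and water (12-qubit
active spaces) it yields 18 and 30 parameters.

**Cost and gradients.**  Circuits conserve the particle sector, so energies
are evaluated in the sector basis with the cached sparse excitation
matrices; the exact gradient is assembled by an adjoint sweep using the
effective Hamiltonian that includes the instantaneous reaction field
(the density-dependent term is quadratic in `gamma`, so its chain rule
collapses onto one extra one-body term).  No frozen-charge approximation is
made within an optimizer step.

**Optimizer.**  Noiseless runs use a monotone adaptive-step gradient
descent (accepted steps never increase the cost; the step grows 1.6x on
success and halves on failure) stopping when an accepted step improves the
cost by less than 1e-8 Ha; each iteration of the solvated run is one full
cycle of the five-step loop (prepare, measure, update charges, evaluate,
step), with the response matrix built once per run.  The iteration counts
printed by this optimizer are single parameter updates and are therefore
not comparable to outer-cycle counts of other implementations.  L-BFGS-B
and COBYLA (the derivative-free path used for noisy cost functions) are
selectable.

## Noise and measurement model

A generic parameterized stand-in for hardware noise: after every excitation
gate, two-qubit depolarizing channels of strength `p2` on the rotated wire
pairs and single-qubit depolarizing `p1` on each touched wire (full-twirl
convention: `p = 1` replaces the marginal by the maximally mixed state);
independent per-qubit readout bit-flips `p_readout` on the sampled
bitstrings.  Expectation values are estimated by rotating each Hermitian
Pauli string to its eigenbasis and sampling bitstrings (8192 shots by
default); each distinct string is measured once per cost evaluation.  Error
bars use the conservative per-string bound sigma = 1/sqrt(shots) propagated
through the Pauli coefficients, not empirical variances.  Sampled 1-RDMs are
rescaled so their trace equals the electron count; no further mitigation
(purification, post-selection) is applied.  The noisy solvation experiment
runs two independent COBYLA optimizations (gas and solvated) from uniform
(-0.1, 0.1) starting angles and reports the tail-averaged difference, plus
the cheaper polarization-energy shortcut that needs only the 1-RDM strings
(18 strings vs 65 for the full six-qubit Hamiltonian).

## Problem sizes and numerical choices

All benchmark systems are minimal-basis: H3+ (6 qubits, 9 determinants),
BeH2 and H2O (12-qubit active spaces with the Be/O 1s core frozen, 225
determinants; all-electron FCI spaces 1225 and 441).  Cavities hold roughly
1600-2300 tesserae at the default tessellation level 3.  Geometry templates
enforce molecular symmetry exactly, and equilibrium parameters are located
by bounded scalar minimization (Nelder-Mead for water's two parameters) of
the all-electron FCI energy to 1e-5 angstrom; the level of theory behind
externally published geometries is not always stated, so optimizing
internally keeps gas-phase anchor energies stationary-robust at the
0.1-1 mHa level.  The water dissociation scan uses the exact-diagonalization
route by default (the variational route is available per point with an
iteration budget that grows with bond length); both obey the variational
bound `Delta G <= U_pol` at every grid point.  Degenerate inputs guarded
explicitly: coincident nuclei, coincident tesserae, fully buried spheres
(logged, skipped), non-positive 1-RDM traces, and odd register sizes all
raise informative errors.

## Known limitations

* Only electrostatics: no cavitation, dispersion or repulsion terms, so the
  computed `Delta G_solv` is the polarization part only.
* s/p Gaussians and the bundled STO-3G tables (H-O); no d functions,
  open-shell references or analytic gradients.
* The icosahedral cavity differs from GePol near sphere-intersection seams.
  One observable consequence: along the water double stretch the
  polarization-energy minimum falls at 0.5 angstrom on a 0.1 angstrom grid,
  one step short of the 0.6 angstrom reported with GePol cavities - the
  location is controlled by when the hydrogen spheres become solvent
  inaccessible, and is the one benchmark this construction does not
  reproduce exactly.
* The solvation free energy of BeH2 is hypersensitive to the beryllium
  sphere radius (~2.3 eV per angstrom); with the hydrogen-calibrated
  default radii our result tracks coupled-cluster-quality references rather
  than the stronger value some FCI-based tables report.
* The noise model is generic (depolarizing + readout); it is not calibrated
  to any specific device, so noisy results are qualitative.
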