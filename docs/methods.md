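# Methods

`crystalrism` solves the three-dimensional reference interaction site model
(3D-RISM) for a rigid solute that is periodically replicated — a molecular
crystal's unit cell, or a single molecule in a periodic box.  This note
records the model, the numerical choices, and what the synthetic test
systems do and do not establish.

## Model

The solvent is described by per-site number densities `rho_g g_g(r)` on a
regular grid covering the unit cell once.  Two relations close the problem:

* the site–site Ornstein–Zernike (OZ) equation
  `h_g(r) = sum_a c_a(r) * chi_ag(r)`, a periodic convolution against the
  bulk solvent susceptibility `chi_ag = omega_ag + rho_a h_ag` precomputed
  by a 1D stage; and
* a closure, `h = exp(t) - 1` for `t < 0` with
  `t = -beta u_PME + h_OZ - c`, and on the positive branch either the full
  exponential (HNC) or its order-n Taylor truncation (PSE-n; PSE-1 is the
  Kovalenko–Hirata closure).  The bridge function is zero throughout.

The solute enters through per-site grid potentials `u_PME_g`: smooth
particle-mesh Ewald electrostatics (cardinal B-spline charge spreading,
Gaussian-screened `4 pi/k^2` reciprocal kernel, erfc real-space complement)
plus minimum-image Lennard-Jones with Lorentz–Berthelot mixing.

### Net-charged solutes

SPME zeroes the `k = 0` mode, which silently adds a uniform neutralizing
background charge `-Q_solute/V_cell`.  Folding the (divergent) background
potential into the direct correlation function defines a renormalized
`c~ = c - beta q_g phi_bk`, whose only surviving effect is a per-site
constant added to `h_OZ` each cycle:

    h_bk_g = -4 pi beta k_e (Q_solute/V_cell) * lim_{k->0} sum_a q_a chi_ag(k)/k^2.

The limit is evaluated by Neville polynomial extrapolation (5 smallest
radial nodes, in the k^2 variable, with a degree-consistency check; real
solvent tables settle to ~3e-7 relative).  With this shift the converged
ion distribution exactly neutralizes the solute: the package verifies
`sum_g q_g rho_g int h_g dr = -Q` to ~1e-6 e on toy ions.  The shift is
identically zero for neutral solutes and for ion-free solvents.

### Excess chemical potential

For HNC-family closures the excess chemical potential has a closed form.
Re-deriving the Kirkwood charging identity for the shifted equations gives

    dmu = kT sum_g rho_g int [ h^2/2 - (1 + h_bk/2) c~ - h c~/2
                               - Theta(t) t^{n+1}/(n+1)! ] dr,

where the last term is the PSE-n truncation correction (absent for HNC) and
the `h_bk`-proportional piece is the background correction, reported
separately.  Note the sign of the background piece: the derivation here
gives `-(1/2) h_bk c~` inside the bracket.  Two independent checks pin it
down: analytic forces agree with 1e-4 Å central differences only with this
sign (and are off by exactly twice the background-term gradient with the
opposite one), and the Kirkwood charging quadrature reproduces the closed
form to ~1e-4 relative.

### Forces

The gradient of dmu with respect to an atom position reduces, for every
closure in the family, to

    dDmu/dR_i = sum_g rho_g int g_g(r) du_PME_g(r)/dR_i dr,

independent of `h_bk`.  The implementation contracts this exactly against
the same discretization used to build `u_PME` (B-spline derivative weights
for the reciprocal part, direct voxel sums for erfc and LJ), so the
analytic gradient is the exact derivative of the discrete dmu functional.
Consequence: finite-difference agreement is limited only by solver
convergence (measured MAE is proportional to the residual tolerance —
1.7e-5 kcal/mol-Å at 1e-11 — with no grid-spacing floor down to 1e-6), not
by the grid.  The package stores gradients with the `+dDmu/dR` sign; MD or
minimization callers negate.

### Finite-size correction

For a single ion in a cubic box the periodic result relates to the
infinite-dilution one through the Wigner lattice term
`dmu_ion = dmu_periodic - q^2 zeta k_e / (2 L)`, `zeta = 2.8372975`.
`wigner_constant()` recomputes zeta from a splitting-invariant Ewald
summation; `wigner_correct()` refuses non-cubic cells (the constant is
lattice-specific).  On a +1e toy ion in 0.1 M salt over L = 40–120 Å the
fitted 1/L slope agrees with `q^2 zeta k_e/2` to 0.7% and the corrected
values are box-size stable to <0.1 kcal/mol.

## Numerics

* **Units**: Å, kcal/mol, elementary charges; Coulomb constant
  332.0522173 kcal·Å/(mol·e²) (Amber convention); LJ stored as
  (epsilon, r_min/2), sigma converted on input.
* **Grids**: triclinic cells supported throughout; fields are indexed along
  the lattice vectors, voxel centers at fractional (i/n1, j/n2, k/n3)
  starting at the origin.  Auto-selected dims are the smallest
  2^a 3^b 5^c 7^d sizes reaching the requested spacing (default 0.5 Å).
* **SPME**: spline order 4 default, 6 recommended for high-accuracy
  potentials (order 6 at 0.2 Å spacing matches a direct Ewald oracle to
  <1e-6 kcal/(mol·e)); splitting width solved from
  `erfc(b r_c)/r_c = direct_tolerance` (1e-9) at the 9 Å default cutoff.
* **LJ tail**: truncated AND shifted at the cutoff.  Plain truncation makes
  dmu discontinuous in atom positions at the voxel level, which pollutes
  1e-4 Å finite differences with O(1e-2) noise from voxels crossing the
  cutoff shell; the shift removes this at the cost of a well depth altered
  by `|u(r_c)|` (~1e-3 epsilon at 9 Å).
* **Positive-exponent cap**: the closure exponent is capped (t_cap = 50 in
  3D, 30 in 1D) *during iteration only* — early transients of charged
  systems overshoot wildly before screening builds up.  Solvers verify the
  cap is inactive at the converged fixed point, so it never changes a
  reported solution.
* **Potential clamp**: `u_PME` is capped at +500 kT at atomic cores;
  `exp(-beta u)` is zero there regardless, the cap only protects
  bookkeeping.  dmu is insensitive to the cap above ~100 kT.
* **MDIIS**: classic control flow — FIFO history (5 vectors), step 0.7,
  restart from the best-ever iterate when the residual exceeds 10x the best.
  The residual is the pooled RMS of `h_closure - h_OZ` over all sites and
  voxels.  Default tolerance 1e-6 for thermodynamics; use <=1e-10 when
  gradients are needed (FD agreement scales with it).
* **1D stage**: dr = 0.025 Å, 32768 points, tolerance 1e-12 by default
  (fixtures use 8192 points, which keeps the electroneutrality defect at
  ~6e-8 e).  The iteration is a damped Picard warmup followed by
  Newton–Krylov (scipy lgmres): the long-wavelength dielectric modes of
  3-site water make plain fixed-point iteration effectively
  non-contractive (Jacobian amplification ~1e4), while Newton–Krylov
  converges it to 1e-12 RMS in seconds.  Ionic solvents use the standard
  erf-split Coulomb renormalization (analytic `4 pi k_e q q e^{-k^2/4a^2}/k^2`
  long-range transform; a = 1 Å⁻¹); bare truncation never converges.
  DRISM dielectric consistency is not implemented (plain XRISM only);
  requesting it raises.
* **Closure applicability**: pure 3-site water under HNC does not converge
  in XRISM (known), and 3D HNC loses its solution for strongly charged
  solutes (a PSE-n continuation stalls between n = 3 and n = 5) — known
  HNC non-existence at strong coupling.  KH is therefore the default and
  the recommended closure for charged systems; HNC works for neutral toys.

## Charging-quadrature validation path

The Kirkwood charging oracle integrates `sum_g rho_g int u_PME g(lambda)`
along `u(lambda) = lambda u_PME` with the background shift scaled by
lambda.  Two refinements make the comparison exact rather than approximate:

1. the lambda-dependent shift generates a path term
   `-kT sum_g rho_g h_bk_g int_0^1 dlambda int c~_g dr`, accumulated from
   the oracle's own trajectory (zero for neutral solutes); and
2. the clamped repulsive cores create a boundary layer of width
   `~1/(beta u_max)` near lambda = 0 that Gauss–Legendre cannot resolve;
   the oracle substitutes `lambda = s^4` (24 nodes) and both routes use a
   consistent 300 kT clamp.

With both, neutral and charged toys agree with the closed form to ~1e-4
relative (the acceptance criterion is 0.5%).

## Synthetic solvents — what green tests do and do not establish

The fixtures provide a single-site LJ fluid (rho sigma^3 = 0.4), a rigid
3-site water-like model (SPC/E-like charges and geometry, 0.0333 Å⁻³), and
aqueous 1:1 salt (water + Na/Cl-like ions at 0.1–1 M).  The salt toys are
*aqueous* because bare vacuum ions at 298 K (Bjerrum length ~560 Å) have no
HNC/KH solution and would be a meaningless solvent; the water sites provide
the dielectric screening, exactly as in the reference calculations.

These toys exercise every code path (multi-site molecular solvents, ionic
screening, charged solutes up to |Q| = 4 e, triclinic plumbing) at
desk scale.  They do not establish force-field realism: no attempt is made
to reproduce Amber parameterization of real biomolecules, experimental
solvation free energies, or crystallographic observables.  Reproducing the
published full-scale RNA numbers would require the deposited structures
plus their Amber topologies, which the offline test environment does not
have.

## Known limitations

* DRISM (dielectrically consistent 1D-RISM) is absent; the water-like
  model's dielectric constant is whatever XRISM/KH gives it.
* No space-group symmetry: the solute must be the full unit-cell content.
* No dispersion PME (LJ is cutoff-based), no polarizable or flexible
  solvent models, no energy/entropy decomposition.
* The Wigner correction is cubic-cell only.
* HNC on strongly charged solutes fails by non-existence, not by a solver
  defect; use KH/PSE-n (matching the reference implementation's practice).
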