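"""Post-converged observables: excess chemical potential (with its separable
background term), excess particle numbers, analytic solvation forces with a
finite-difference validator, and the Wigner finite-size correction.

Sign convention: ``solvation_forces`` returns the *gradient* dDmu/dR_i;
an MD or minimization caller negates it to obtain the force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.special import erfc

from .closures import ClosureSpec, background_term as _background_term, mu_integrand
from .constants import COULOMB
from .grid import integrate
from .potential import contract_potential_gradient
from .solver import RismState, solve_3drism, solvent_excess_charge

__all__ = [
    "ThermoReport",
    "excess_chemical_potential",
    "excess_numbers",
    "solvation_forces",
    "finite_difference_gradient",
    "wigner_correct",
    "wigner_constant",
    "WignerCorrection",
]


@dataclass
class ThermoReport:
    delta_mu: float                     # kcal/mol
    background_term: float              # kcal/mol, included in delta_mu
    excess_numbers: dict                # site label -> dimensionless count
    forces: np.ndarray | None = None    # (n_atoms, 3) gradient, kcal/(mol·Å)
    solvent_excess_charge: float = 0.0  # e
    solute_charge: float = 0.0          # e
    closure: str = ""
    grid_dims: tuple = ()
    residual: float = np.nan
    iterations: int = 0

    @property
    def neutrality_defect(self) -> float:
        """|sum_g q_g N_ex_g + Q_solute| in e."""
        return abs(self.solvent_excess_charge + self.solute_charge)

    def to_dict(self) -> dict:
        d = {
            "schema_version": 1,
            "delta_mu_kcal_mol": self.delta_mu,
            "background_term_kcal_mol": self.background_term,
            "solute_charge_e": self.solute_charge,
            "solvent_excess_charge_e": self.solvent_excess_charge,
            "neutrality_defect_e": self.neutrality_defect,
            "closure": self.closure,
            "grid_dims": list(self.grid_dims),
            "residual": self.residual,
            "iterations": self.iterations,
            "excess_numbers": dict(self.excess_numbers),
        }
        if self.forces is not None:
            d["force_gradients_kcal_mol_A"] = np.asarray(self.forces).tolist()
        return d


def _require_converged(state: RismState):
    if not state.converged:
        raise RuntimeError(
            f"state not converged (residual {state.residual:.3e} > "
            f"tolerance {state.tolerance:.1e}); refusing thermodynamics"
        )


def excess_chemical_potential(state: RismState, include_background: bool = True):
    """Closed-form excess chemical potential of the converged state.

    Returns (delta_mu, background) in kcal/mol; ``background`` is the
    separable term caused by the uniform-background renormalization and is
    exactly zero for neutral solutes.  ``include_background=False`` omits it
    from delta_mu (diagnostic use only — the omission is *wrong* for charged
    solutes and visibly degrades force/finite-difference agreement).
    """
    _require_converged(state)
    solvent = state.solvent
    beta = solvent.beta
    kT = 1.0 / beta
    total = 0.0
    for g, s in enumerate(solvent.sites):
        h_bk = state.shift[g] if include_background else 0.0
        dens = mu_integrand(state.h[g], state.c_tilde[g], h_bk,
                            state.closure, t=state.t[g])
        total += kT * s.density * integrate(dens, state.cell, state.grid)
    background = _background_term(
        state.c_tilde, state.shift.values if include_background else
        np.zeros(solvent.n_sites), solvent.densities, beta,
        state.cell, state.grid)
    return float(total), float(background)


def excess_numbers(state: RismState) -> dict:
    """N_ex_g = rho_g int h_g dr per site (negative = depletion)."""
    out = {}
    for g, s in enumerate(state.solvent.sites):
        out[s.label] = float(s.density * integrate(state.h[g], state.cell, state.grid))
    return out


def solvation_forces(state: RismState, force_tolerance: float = 1e-8) -> np.ndarray:
    """Analytic per-atom gradients dDmu/dR_i = sum_g rho_g int g_g du/dR_i dr.

    The formula is identical for every closure in the HNC/PSE family and
    independent of h_bk.  Needs a tightly converged state.
    """
    _require_converged(state)
    if state.residual > force_tolerance:
        warnings.warn(
            f"state converged only to {state.residual:.1e}; gradient/"
            f"finite-difference agreement degrades above {force_tolerance:.0e}"
        )
    return contract_potential_gradient(
        state.solute, state.g, state.solvent.sites,
        state.solvent.densities, state.cell, state.grid, state.ewald)


def thermo_report(state: RismState, forces: bool = False) -> ThermoReport:
    dmu, bk = excess_chemical_potential(state)
    return ThermoReport(
        delta_mu=dmu,
        background_term=bk,
        excess_numbers=excess_numbers(state),
        forces=solvation_forces(state) if forces else None,
        solvent_excess_charge=solvent_excess_charge(state),
        solute_charge=state.solute.net_charge if state.solute else 0.0,
        closure=str(state.closure),
        grid_dims=state.grid.dims,
        residual=state.residual,
        iterations=state.iterations,
    )


def finite_difference_gradient(state: RismState, atoms=None,
                               displacement: float = 1e-4,
                               include_background: bool = True) -> np.ndarray:
    """Central-difference gradient of delta_mu for the selected atoms
    (2 solves per Cartesian component, warm-started from ``state``).

    Validation tool only.  ``include_background=False`` reproduces the
    known failure mode where omitting the background term ruins agreement
    with the analytic gradients.
    """
    _require_converged(state)
    if atoms is None:
        atoms = range(state.solute.n_atoms)
    atoms = list(atoms)
    cfg = state_mdiis_config(state)
    grad = np.zeros((len(atoms), 3))
    for row, i in enumerate(atoms):
        for comp in range(3):
            vals = []
            for sgn in (+1.0, -1.0):
                delta = np.zeros(3)
                delta[comp] = sgn * displacement
                solute_d = state.solute.displaced(i, delta)
                st = solve_3drism(
                    solute_d, state.solvent, state.cell, state.grid,
                    closure=state.closure, mdiis_config=cfg,
                    initial_c=state.c_tilde, ewald=state.ewald)
                dmu, _ = excess_chemical_potential(
                    st, include_background=include_background)
                vals.append(dmu)
            grad[row, comp] = (vals[0] - vals[1]) / (2.0 * displacement)
    return grad


def state_mdiis_config(state: RismState):
    from .mdiis import MDIISConfig

    return MDIISConfig(tolerance=state.tolerance,
                       max_iterations=20000)


# --------------------------------------------------------------------------
# Wigner finite-size machinery
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WignerCorrection:
    q: float
    L: float
    zeta: float = 2.8372975

    @property
    def value(self) -> float:
        """-q^2 zeta k_e / (2 L), kcal/mol (negative for q != 0)."""
        return -self.q * self.q * self.zeta * COULOMB / (2.0 * self.L)


def wigner_correct(delta_mu_periodic: float, q: float, L_or_cell,
                   zeta: float | None = None) -> float:
    """Dmu_ion = Dmu_periodic - q^2 zeta k_e / (2 L) for a cubic cell."""
    from .grid import UnitCell

    if isinstance(L_or_cell, UnitCell):
        if not L_or_cell.is_cubic():
            raise ValueError("the Wigner correction as used here is for cubic "
                             "cells only")
        L = float(L_or_cell.lattice[0, 0])
    else:
        L = float(L_or_cell)
    if zeta is None:
        zeta = WignerCorrection(q, L).zeta
    return delta_mu_periodic + WignerCorrection(q, L, zeta).value


def _wigner_energy(beta_split: float) -> float:
    """Ewald self-energy of a unit point charge with uniform neutralizing
    background in a unit cube (k_e = 1)."""
    b = beta_split
    # real-space image sum
    nmax = int(np.ceil(8.0 / b)) + 1
    rng = np.arange(-nmax, nmax + 1)
    N = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    r = np.sqrt((N * N).sum(axis=1))
    r = r[r > 0]
    real = 0.5 * (erfc(b * r) / r).sum()
    # reciprocal sum, k = 2 pi m, V = 1
    mmax = int(np.ceil(8.0 * b / np.pi)) + 1
    rng = np.arange(-mmax, mmax + 1)
    M = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    k2 = 4.0 * np.pi ** 2 * (M * M).sum(axis=1)
    k2 = k2[k2 > 0]
    recip = 0.5 * (4.0 * np.pi / k2 * np.exp(-k2 / (4.0 * b * b))).sum()
    self_term = -b / np.sqrt(np.pi)
    background = -np.pi / (2.0 * b * b)  # charged-cell term -pi (sum q)^2 / (2 V b^2), V=1
    return real + recip + self_term + background


def wigner_constant(tolerance: float = 1e-8) -> float:
    """Cubic-lattice point-charge constant zeta = -2 L E_self / q^2,
    from a direct Ewald summation; checked for splitting-width invariance."""
    vals = [-2.0 * _wigner_energy(b) for b in (4.0, 6.0)]
    if abs(vals[0] - vals[1]) > tolerance * max(abs(vals[0]), 1.0):
        raise ArithmeticError(
            f"Wigner Ewald sum not converged: {vals[0]!r} vs {vals[1]!r}")
    return float(vals[1])
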