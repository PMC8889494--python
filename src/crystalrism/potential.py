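"""Periodic solute–solvent interaction potentials on the unit-cell grid.

Electrostatics follow the smooth particle-mesh Ewald (SPME) construction:
cardinal-B-spline charge spreading (order 4 or 6), a reciprocal-space
convolution with the Gaussian-screened Green's function 4*pi*exp(-k^2/4b^2)/k^2
(the k=0 mode is zeroed — this *is* the uniform neutralizing background the
solver's h_bk machinery compensates), and a real-space erfc complement
evaluated by minimum image within the cutoff.  Lennard-Jones interactions
are minimum-image with the same cutoff, Lorentz–Berthelot mixing, and are
truncated-and-shifted so the potential is continuous in atom positions
(which keeps finite-difference force checks clean).

The same machinery exposes the contraction of field gradients with any
per-site solvent field, used for analytic solvation forces: the reciprocal
part spreads the charge-weighted solvent density and interpolates back at
the atom through B-spline derivative weights; the erfc and LJ parts are
direct voxel sums within the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfc

from .constants import COULOMB
from .grid import GridSpec, SiteFieldSet, UnitCell, kvectors

__all__ = [
    "SoluteAtom",
    "Solute",
    "EwaldParams",
    "bspline_values",
    "spread_charges",
    "reciprocal_potential",
    "site_potentials",
    "contract_potential_gradient",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SoluteAtom:
    position: tuple
    charge: float
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0
    label: str = ""

    def __post_init__(self):
        pos = tuple(float(x) for x in self.position)
        if len(pos) != 3 or not all(np.isfinite(pos)):
            raise ValueError(f"atom {self.label!r}: non-finite position {pos}")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.label!r}: lj_epsilon must be >= 0")
        object.__setattr__(self, "position", pos)


@dataclass
class Solute:
    atoms: list

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], float).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], float)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum()) if self.atoms else 0.0

    def displaced(self, i: int, delta) -> "Solute":
        """Copy with atom i moved by delta (used by finite differences)."""
        atoms = list(self.atoms)
        a = atoms[i]
        atoms[i] = SoluteAtom(tuple(np.asarray(a.position) + np.asarray(delta)),
                              a.charge, a.lj_epsilon, a.lj_rmin_half, a.label)
        return Solute(atoms)


@dataclass(frozen=True)
class EwaldParams:
    real_cutoff: float = 9.0
    direct_tolerance: float = 1e-9
    spline_order: int = 4
    beta_split: float = field(default=None)  # Å^-1; derived if None

    def __post_init__(self):
        if self.spline_order not in (4, 6):
            raise ValueError("spline_order must be 4 or 6")
        if self.beta_split is None:
            object.__setattr__(
                self, "beta_split",
                beta_from_tolerance(self.real_cutoff, self.direct_tolerance),
            )
        check = erfc(self.beta_split * self.real_cutoff) / self.real_cutoff
        if check > 10.0 * self.direct_tolerance:
            raise ValueError(
                f"erfc(beta*rc)/rc = {check:.3g} exceeds direct_tolerance"
            )


def beta_from_tolerance(real_cutoff: float, tol: float) -> float:
    """Splitting width such that erfc(beta*rc)/rc == tol (bisection)."""
    f = lambda b: erfc(b * real_cutoff) / real_cutoff - tol
    return float(brentq(f, 1e-4, 20.0, xtol=1e-12))


# --------------------------------------------------------------------------
# cardinal B-splines
# --------------------------------------------------------------------------

def _cardinal_bspline(n: int, x: np.ndarray) -> np.ndarray:
    """M_n(x) on support (0, n), zero outside."""
    x = np.asarray(x, float)
    if n == 2:
        return np.where((x > 0) & (x < 2), 1.0 - np.abs(x - 1.0), 0.0)
    mm = _cardinal_bspline(n - 1, x)
    mm1 = _cardinal_bspline(n - 1, x - 1.0)
    return (x * mm + (n - x) * mm1) / (n - 1)


def bspline_values(order: int, frac: np.ndarray):
    """Spreading weights and derivative weights for fractional offsets.

    ``frac`` in [0, 1) is u - floor(u); returns (w, dw) of shape
    frac.shape + (order,), where entry l corresponds to grid point
    floor(u) - l, with weight M_n(frac + l) and derivative dM_n/du.
    """
    frac = np.asarray(frac, float)
    ls = np.arange(order)
    x = frac[..., None] + ls
    w = _cardinal_bspline(order, x)
    dw = _cardinal_bspline(order - 1, x) - _cardinal_bspline(order - 1, x - 1.0)
    return w, dw


def _euler_spline_factors(order: int, dims):
    """Per-axis complex b(m) deconvolution factors (rfft layout on last axis)."""
    factors = []
    for ax, K in enumerate(dims):
        m = np.arange(K) if ax < 2 else np.arange(dims[2] // 2 + 1)
        ls = np.arange(order - 1)
        denom = (_cardinal_bspline(order, ls + 1.0)[None, :]
                 * np.exp(2j * np.pi * np.outer(m, ls) / K)).sum(axis=1)
        b = np.exp(2j * np.pi * (order - 1) * m / K) / denom
        factors.append(b)
    b1, b2, b3 = factors
    return b1[:, None, None] * b2[None, :, None] * b3[None, None, :]


def _spread_indices(cell: UnitCell, grid: GridSpec, positions, order: int):
    """Per-atom spline support: grid indices (natoms, order, 3 axes) and
    weight/derivative tables (natoms, 3, order)."""
    dims = np.array(grid.dims)
    f = (np.asarray(positions, float) @ cell.inverse) % 1.0
    u = f * dims  # grid units
    j0 = np.floor(u).astype(int)
    frac = u - j0
    w, dw = bspline_values(order, frac)          # (natoms, 3, order)
    idx = (j0[..., None] - np.arange(order)[None, None, :]) % dims[:, None]
    return idx, w, dw


def spread_charges(solute: Solute, cell: UnitCell, grid: GridSpec,
                   spline_order: int = 4) -> np.ndarray:
    """Interpolate atomic charges onto the grid with cardinal B-splines.

    Partition of unity guarantees the grid total equals the net charge.
    """
    Q = np.zeros(grid.dims)
    if solute.n_atoms == 0:
        return Q
    idx, w, _ = _spread_indices(cell, grid, solute.positions, spline_order)
    charges = solute.charges
    n = spline_order
    for a in range(solute.n_atoms):
        wx = charges[a] * w[a, 0]
        wxy = np.outer(wx, w[a, 1])
        block = wxy[:, :, None] * w[a, 2][None, None, :]
        np.add.at(Q, np.ix_(idx[a, 0], idx[a, 1], idx[a, 2]), block)
    return Q


def _green_function(cell: UnitCell, grid: GridSpec, beta_split: float):
    """G(k) = 4*pi*k_e*exp(-k^2/4b^2)/(V k^2), k=0 zeroed (rfft layout)."""
    _, k2 = kvectors(cell, grid, half=True)
    G = np.zeros_like(k2)
    nz = k2 > 0
    G[nz] = 4.0 * np.pi * COULOMB * np.exp(
        -k2[nz] / (4.0 * beta_split ** 2)) / (cell.volume * k2[nz])
    return G


def reciprocal_potential(charge_grid: np.ndarray, cell: UnitCell, grid: GridSpec,
                         beta_split: float, spline_order: int = 4) -> np.ndarray:
    """Reciprocal-space SPME potential at voxel centers (kcal/(mol·e)).

    Deconvolves the B-spline spreading once (the evaluation points are the
    voxel centers themselves, so no second interpolation is applied).
    """
    G = _green_function(cell, grid, beta_split)
    B = _euler_spline_factors(spline_order, grid.dims)
    phi_hat = G * np.conj(B) * np.fft.rfftn(charge_grid)
    return np.fft.irfftn(phi_hat, s=grid.dims, axes=(0, 1, 2)) * grid.npoints


# --------------------------------------------------------------------------
# real-space (minimum image, cutoff) accumulation
# --------------------------------------------------------------------------

def _cutoff_steps(cell: UnitCell, grid: GridSpec, rc: float) -> np.ndarray:
    lat = cell.lattice
    widths = []
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        nvec = np.cross(lat[j], lat[k])
        widths.append(abs(np.dot(lat[i], nvec)) / np.linalg.norm(nvec))
    return np.array([int(np.ceil(rc * n / w)) + 1
                     for n, w in zip(grid.dims, widths)])


def _atom_voxel_block(cell, grid, position, rc):
    """Voxel indices and displacement vectors (voxel - atom) within the
    cutoff of one atom, enumerated without wrapping so each voxel appears
    with its nearest image."""
    dims = np.array(grid.dims)
    steps = _cutoff_steps(cell, grid, rc)
    f = np.asarray(position, float) @ cell.inverse
    j0 = np.round(f * dims).astype(int)
    ranges = [np.arange(j0[i] - steps[i], j0[i] + steps[i] + 1) for i in range(3)]
    J = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    disp = (J / dims - f) @ cell.lattice
    d2 = np.einsum("ij,ij->i", disp, disp)
    mask = d2 <= rc * rc
    J = J[mask] % dims
    return J, disp[mask], np.sqrt(d2[mask])


def _erfc_shifted(d, beta_split, rc):
    v = erfc(beta_split * d) / d
    return v - erfc(beta_split * rc) / rc


def _lj_shifted(d, eps, rmin, rc):
    x6 = (rmin / d) ** 6
    xc6 = (rmin / rc) ** 6
    return eps * (x6 * x6 - 2.0 * x6) - eps * (xc6 * xc6 - 2.0 * xc6)


def site_potentials(solute: Solute, solvent_sites, cell: UnitCell, grid: GridSpec,
                    ewald: EwaldParams, clamp: float = None) -> SiteFieldSet:
    """Per-solvent-site periodic potential u_PME_g = q_g*phi_PME + u_LJ_g.

    ``solvent_sites`` is any sequence with .charge/.lj_epsilon/.lj_rmin_half
    (e.g. BulkSolvent.sites).  ``clamp`` caps the potential (kcal/mol) at
    atomic cores; exp(-beta*u) is zero there regardless, the cap only
    protects downstream bookkeeping from overflow.
    """
    rc = ewald.real_cutoff
    if rc > 0.5 * cell.min_width():
        import warnings
        warnings.warn(
            f"cutoff {rc} exceeds half the minimum cell width "
            f"{0.5 * cell.min_width():.2f}; minimum-image results are approximate"
        )
    n_sites = len(solvent_sites)
    q_sites = np.array([s.charge for s in solvent_sites])

    # electrostatics: reciprocal part once, erfc part accumulated per atom
    phi = np.zeros(grid.dims)
    if np.any(solute.charges != 0.0):
        Q = spread_charges(solute, cell, grid, ewald.spline_order)
        phi = reciprocal_potential(Q, cell, grid, ewald.beta_split,
                                   ewald.spline_order)
    lj = np.zeros((n_sites,) + grid.dims)
    erfc_grid = np.zeros(grid.dims)
    for a in range(solute.n_atoms):
        atom = solute.atoms[a]
        J, disp, d = _atom_voxel_block(cell, grid, atom.position, rc)
        d = np.maximum(d, 1e-12)
        jx, jy, jz = J[:, 0], J[:, 1], J[:, 2]
        if atom.charge != 0.0:
            np.add.at(erfc_grid, (jx, jy, jz),
                      COULOMB * atom.charge * _erfc_shifted(d, ewald.beta_split, rc))
        for g, s in enumerate(solvent_sites):
            eps = np.sqrt(atom.lj_epsilon * s.lj_epsilon)
            rmin = atom.lj_rmin_half + s.lj_rmin_half
            if eps > 0.0 and rmin > 0.0:
                np.add.at(lj[g], (jx, jy, jz), _lj_shifted(d, eps, rmin, rc))
    phi += erfc_grid

    fields = q_sites[:, None, None, None] * phi[None] + lj
    if clamp is not None:
        np.minimum(fields, clamp, out=fields)
    return SiteFieldSet(fields, role="u_pme",
                        site_labels=[getattr(s, "label", str(i))
                                     for i, s in enumerate(solvent_sites)])


# --------------------------------------------------------------------------
# gradient contraction (Eq.-17-style force route)
# --------------------------------------------------------------------------

def contract_potential_gradient(solute: Solute, site_fields, solvent_sites,
                                densities, cell: UnitCell, grid: GridSpec,
                                ewald: EwaldParams,
                                spline_order: int | None = None) -> np.ndarray:
    """Per-atom contraction sum_g rho_g int F_g(r) d u_PME_g / d R_i dr.

    With F = g (the converged distribution functions) this is the analytic
    gradient of the excess chemical potential with respect to atom positions.
    Returns an (n_atoms, 3) array in kcal/(mol·Å).
    """
    if spline_order is not None and spline_order != ewald.spline_order:
        raise ValueError(
            f"gradient spline order {spline_order} inconsistent with the "
            f"potential's order {ewald.spline_order}"
        )
    order = ewald.spline_order
    rc = ewald.real_cutoff
    F = np.asarray(site_fields.fields if isinstance(site_fields, SiteFieldSet)
                   else site_fields, float)
    rho = np.asarray(densities, float)
    q_sites = np.array([s.charge for s in solvent_sites])
    dV = grid.voxel_volume(cell)
    natoms = solute.n_atoms
    grad = np.zeros((natoms, 3))
    if natoms == 0 or not np.any(F):
        return grad

    # --- reciprocal part: psi = kernel adjoint applied to the charge-weighted
    # solvent density, then B-spline derivative weights at each atom
    w_density = np.tensordot(rho * q_sites, F, axes=(0, 0))
    if np.any(w_density) and np.any(solute.charges != 0.0):
        G = _green_function(cell, grid, ewald.beta_split)
        B = _euler_spline_factors(order, grid.dims)
        Gc = G * np.conj(B)
        psi = np.fft.irfftn(np.conj(Gc) * np.fft.rfftn(w_density),
                            s=grid.dims, axes=(0, 1, 2)) * grid.npoints * dV
        idx, w, dw = _spread_indices(cell, grid, solute.positions, order)
        dims = np.array(grid.dims)
        # du_axis/dR_cart = dims[axis] * inverse[:, axis]
        du_dR = cell.inverse * dims[None, :]  # (cart 3, axis 3)
        for a in range(natoms):
            qa = solute.charges[a]
            if qa == 0.0:
                continue
            block = psi[np.ix_(idx[a, 0], idx[a, 1], idx[a, 2])]
            gx = np.einsum("i,j,k,ijk->", dw[a, 0], w[a, 1], w[a, 2], block)
            gy = np.einsum("i,j,k,ijk->", w[a, 0], dw[a, 1], w[a, 2], block)
            gz = np.einsum("i,j,k,ijk->", w[a, 0], w[a, 1], dw[a, 2], block)
            grad[a] += qa * (du_dR @ np.array([gx, gy, gz]))

    # --- real-space erfc + LJ parts: direct voxel sums within the cutoff
    beta_s = ewald.beta_split
    two_over_sqrtpi = 2.0 / np.sqrt(np.pi)
    for a in range(natoms):
        atom = solute.atoms[a]
        J, disp, d = _atom_voxel_block(cell, grid, atom.position, rc)
        if len(d) == 0:
            continue
        d = np.maximum(d, 1e-10)
        jx, jy, jz = J[:, 0], J[:, 1], J[:, 2]
        # v'(d) coefficients; dU/dR_i = -v'(d) * disp/d  (disp = r - R_i)
        vp = np.zeros_like(d)
        if atom.charge != 0.0:
            qw = (rho * q_sites) @ F[:, jx, jy, jz]
            vp_el = COULOMB * atom.charge * (
                -two_over_sqrtpi * beta_s * np.exp(-(beta_s * d) ** 2) / d
                - erfc(beta_s * d) / d ** 2
            )
            vp += vp_el * qw
        for g, s in enumerate(solvent_sites):
            eps = np.sqrt(atom.lj_epsilon * s.lj_epsilon)
            rmin = atom.lj_rmin_half + s.lj_rmin_half
            if eps > 0.0 and rmin > 0.0:
                x6 = (rmin / d) ** 6
                vp_lj = -12.0 * eps * (x6 * x6 - x6) / d
                vp += vp_lj * rho[g] * F[g, jx, jy, jz]
        grad[a] += dV * ((-vp / d)[:, None] * disp).sum(axis=0)
    return grad
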