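"""Deterministic toy systems and brute-force oracles used in testing.

Everything here is synthetic and desk-scale: point ions and small rigid
molecules in cubic cells, single-site LJ fluids, a 3-site water-like model
and monovalent salt solvents.  The oracles (direct Ewald summation, direct
periodic convolution, Kirkwood charging quadrature) are written
independently of the code paths they validate.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .constants import COULOMB
from .grid import GridSpec, UnitCell, kvectors
from .mdiis import MDIISConfig
from .potential import EwaldParams, Solute, SoluteAtom, site_potentials
from .solvent import (BulkSolvent, RadialGrid, SolventSite, SolventSpecies,
                      solve_rism1d, susceptibility)

__all__ = [
    "ToySystem",
    "make_toy",
    "TOY_CATALOG",
    "salt_species",
    "lj_species",
    "water_like_species",
    "build_solvent",
    "ideal_gas_solvent",
    "direct_ewald_oracle",
    "direct_convolution_oracle",
    "charging_quadrature_oracle",
    "wigner_shell_sum",
]

#: mol/L -> number per Å^3
MOLAR_TO_A3 = 6.02214076e-4


# --------------------------------------------------------------------------
# toy solvent recipes
# --------------------------------------------------------------------------

def salt_species(molar: float = 1.0, water_density: float = 0.0333):
    """Aqueous 1:1 monovalent salt: 3-site water-like solvent plus two
    monatomic ionic species (Na+/Cl- like LJ cores).

    The water sites provide the dielectric screening without which bare
    vacuum ions at room temperature are absurdly strongly coupled (Bjerrum
    length ~560 Å) and the closure equations have no solution.
    """
    rho = molar * MOLAR_TO_A3
    cat = SolventSite("CAT", +1.0, 0.0874, 1.37, rho)
    ani = SolventSite("ANI", -1.0, 0.0356, 2.51, rho)
    return water_like_species(water_density) + [
        SolventSpecies.monatomic(cat), SolventSpecies.monatomic(ani)]


def lj_species(rho_sigma3: float = 0.5, sigma: float = 3.4, eps: float = 0.2):
    """Neutral single-site LJ fluid at reduced density rho*sigma^3."""
    rho = rho_sigma3 / sigma ** 3
    site = SolventSite.from_sigma("LJ", 0.0, eps, sigma, rho)
    return [SolventSpecies.monatomic(site)]


def water_like_species(density: float = 0.0333):
    """Rigid 3-site water-like model (SPC/E-like charges and geometry)."""
    O = SolventSite("OW", -0.8476, 0.1553, 1.7767, density)
    H1 = SolventSite("HW1", 0.4238, 0.0460, 0.70, density)
    H2 = SolventSite("HW2", 0.4238, 0.0460, 0.70, density)
    d_oh = 1.0
    d_hh = 1.633
    dist = np.array([[0.0, d_oh, d_oh],
                     [d_oh, 0.0, d_hh],
                     [d_oh, d_hh, 0.0]])
    return [SolventSpecies((O, H1, H2), dist)]


@functools.lru_cache(maxsize=16)
def _cached_solvent(key, closure, n_points, dr, temperature):
    species = _SPECIES_BUILDERS[key[0]](*key[1:])
    sol = solve_rism1d(species, closure=closure,
                       grid=RadialGrid(dr=dr, n=n_points),
                       temperature=temperature, tolerance=1e-12)
    return susceptibility(sol)


_SPECIES_BUILDERS = {
    "salt": lambda molar: salt_species(molar),
    "lj": lambda rho, sigma, eps: lj_species(rho, sigma, eps),
    "water": lambda density: water_like_species(density),
}


def build_solvent(kind: str = "salt", closure: str = "hnc",
                  n_points: int = 16384, dr: float = 0.025,
                  temperature: float = 298.0, **params) -> BulkSolvent:
    """Solve the 1D stage for a named toy solvent (memoized)."""
    if kind == "salt":
        key = ("salt", params.get("molar", 1.0))
    elif kind == "lj":
        key = ("lj", params.get("rho_sigma3", 0.5), params.get("sigma", 3.4),
               params.get("eps", 0.2))
    elif kind == "water":
        key = ("water", params.get("density", 0.0333))
    elif kind == "ideal":
        return ideal_gas_solvent(temperature=temperature,
                                 **{k: v for k, v in params.items()
                                    if k in ("n_sites", "density")})
    else:
        raise ValueError(f"unknown toy solvent kind {kind!r}")
    return _cached_solvent(key, closure, n_points, dr, temperature)


def ideal_gas_solvent(n_sites: int = 1, density: float = 0.01,
                      temperature: float = 298.0,
                      k_grid=None) -> BulkSolvent:
    """Non-interacting monatomic solvent(s): chi_hat = omega_hat = identity."""
    if k_grid is None:
        k_grid = RadialGrid(dr=0.05, n=4096).k
    species = [SolventSpecies.monatomic(
        SolventSite(f"IG{i}", 0.0, 0.0, 0.0, density)) for i in range(n_sites)]
    chi = np.zeros((n_sites, n_sites, len(k_grid)))
    for i in range(n_sites):
        chi[i, i] = 1.0
    return BulkSolvent(temperature=temperature, species=species,
                       k_grid=np.asarray(k_grid, float), chi_hat=chi,
                       closure="ideal")


# --------------------------------------------------------------------------
# toy solutes
# --------------------------------------------------------------------------

@dataclass
class ToySystem:
    name: str
    solute: Solute
    cell: UnitCell
    solvent_kind: str
    solvent_params: dict = field(default_factory=dict)
    solvent_closure: str = "kh"
    expected: dict = field(default_factory=dict)

    def solvent(self, **overrides) -> BulkSolvent:
        kw = dict(self.solvent_params)
        kw.update(overrides)
        closure = kw.pop("closure", self.solvent_closure)
        return build_solvent(self.solvent_kind, closure=closure, **kw)


def _ion(position, q, label="ION"):
    # soft LJ core keeps closure exponents finite at the nucleus
    return SoluteAtom(tuple(position), q, 0.15, 1.8, label)


def make_toy(name: str, seed: int = 0, **size_params) -> ToySystem:
    """Catalog of deterministic toy systems; regeneration from (name, seed)
    is bit-identical."""
    rng = np.random.default_rng(seed)
    if name == "ideal_gas_probe":
        L = size_params.get("L", 10.0)
        solute = Solute([SoluteAtom((0.45 * L, 0.5 * L, 0.5 * L), 0.0, 0.2, 1.7, "LJ")])
        return ToySystem(name, solute, UnitCell.cubic(L), "ideal", {})
    if name == "lj_atom":
        L = size_params.get("L", 12.0)
        solute = Solute([SoluteAtom((0.5 * L,) * 3, 0.0, 0.25, 1.9, "LJ")])
        return ToySystem(name, solute, UnitCell.cubic(L), "lj",
                         {"rho_sigma3": 0.4}, solvent_closure="hnc")
    if name == "cation_in_salt":
        L = size_params.get("L", 12.0)
        q = size_params.get("q", 1.0)
        molar = size_params.get("molar", 1.0)
        pos = 0.5 * L + 0.05 * rng.standard_normal(3)
        solute = Solute([_ion(pos, q, "CAT")])
        return ToySystem(name, solute, UnitCell.cubic(L), "salt",
                         {"molar": molar}, expected={"Q": q})
    if name == "anion_lattice":
        L = size_params.get("L", 14.0)
        molar = size_params.get("molar", 1.0)
        base = np.array([[0.25, 0.25, 0.25], [0.75, 0.75, 0.25],
                         [0.75, 0.25, 0.75], [0.25, 0.75, 0.75]]) * L
        jitter = 0.05 * rng.standard_normal(base.shape)
        atoms = [_ion(p, -1.0, f"AN{i}") for i, p in enumerate(base + jitter)]
        solute = Solute(atoms)
        return ToySystem(name, solute, UnitCell.cubic(L), "salt",
                         {"molar": molar}, expected={"Q": -4.0})
    if name == "rigid_triatomic_crystal":
        L = size_params.get("L", 12.0)
        molar = size_params.get("molar", 1.0)
        atoms = []
        for shift in ([0.3 * L] * 3, [0.7 * L] * 3):
            c = np.asarray(shift) + 0.03 * rng.standard_normal(3)
            atoms.append(SoluteAtom(tuple(c), -0.8, 0.18, 1.75, "O"))
            atoms.append(SoluteAtom(tuple(c + [0.95, 0.0, 0.0]), 0.4, 0.02, 0.6, "H1"))
            atoms.append(SoluteAtom(tuple(c + [-0.24, 0.92, 0.0]), 0.4, 0.02, 0.6, "H2"))
        return ToySystem(name, Solute(atoms), UnitCell.cubic(L), "salt",
                         {"molar": molar}, expected={"Q": 0.0})
    if name == "box_series":
        raise ValueError("box_series expands to several systems; use make_box_series()")
    raise ValueError(f"unknown toy system {name!r}")


def make_box_series(seed: int = 0, sizes=(40.0, 60.0, 80.0, 120.0),
                    q: float = 1.0, molar: float = 0.1):
    """One +q ion centered in cubic boxes of increasing size (same solvent)."""
    out = []
    for L in sizes:
        solute = Solute([_ion((0.5 * L,) * 3, q, "ION")])
        out.append(ToySystem(f"box_{int(L)}", solute, UnitCell.cubic(L),
                             "salt", {"molar": molar}, expected={"Q": q}))
    return out


TOY_CATALOG = ("ideal_gas_probe", "lj_atom", "cation_in_salt",
               "anion_lattice", "rigid_triatomic_crystal", "box_series")


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def direct_ewald_oracle(charges, positions, cell: UnitCell, points,
                        beta: float = 0.6, tol_digits: float = 1e-8):
    """Classic Ewald potential (tin-foil, k=0 dropped) at arbitrary points by
    explicit real- and reciprocal-space sums; independent of the SPME path.

    Convergence is verified by extending both sums; result in kcal/(mol·e).
    """
    charges = np.asarray(charges, float)
    positions = np.atleast_2d(np.asarray(positions, float))
    points = np.atleast_2d(np.asarray(points, float))
    if len(charges) > 100:
        raise ValueError("oracle is O(N^2); keep <= 100 charges")

    def attempt(beta_s, extra=0):
        # real-space over explicit images
        span = 8.0 / beta_s
        widths = [cell.min_width()]
        n_img = int(np.ceil(span / min(widths))) + 1 + extra
        rng = np.arange(-n_img, n_img + 1)
        shifts = (np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1)
                  .reshape(-1, 3) @ cell.lattice)
        phi = np.zeros(len(points))
        for qi, Ri in zip(charges, positions):
            d = points[:, None, :] - (Ri[None, None, :] + shifts[None, :, :])
            r = np.sqrt(np.einsum("pnx,pnx->pn", d, d))
            r = np.where(r < 1e-12, np.inf, r)
            phi += qi * (erfc(beta_s * r) / r).sum(axis=1)
        # reciprocal space
        inv = cell.inverse
        kmax = 2.0 * beta_s * np.sqrt(np.log(1.0 / 1e-14))
        blen = 2.0 * np.pi * np.linalg.norm(inv, axis=0)
        mmax = np.ceil(kmax / blen).astype(int) + 1 + extra
        grids = [np.arange(-m, m + 1) for m in mmax]
        M = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
        K = 2.0 * np.pi * (M @ inv.T)
        k2 = np.einsum("mx,mx->m", K, K)
        sel = k2 > 1e-12
        K, k2 = K[sel], k2[sel]
        S = (charges[None, :] *
             np.exp(-1j * (K @ positions.T))).sum(axis=1)
        coef = 4.0 * np.pi / (cell.volume * k2) * np.exp(-k2 / (4.0 * beta_s ** 2))
        phases = np.exp(1j * (points @ K.T))
        phi += (phases * (coef * S)[None, :]).sum(axis=1).real
        return COULOMB * phi

    a = attempt(beta)
    b = attempt(beta, extra=2)
    if np.max(np.abs(a - b)) > tol_digits * max(1.0, np.max(np.abs(b))):
        raise ArithmeticError("direct Ewald oracle not converged")
    return b


def direct_convolution_oracle(c_fields, solvent: BulkSolvent, cell: UnitCell,
                              grid: GridSpec, shift_values=None) -> np.ndarray:
    """O(N^2) periodic convolution h_g = sum_a c_a * chi_ag + h_bk_g.

    The direct-space kernel is built mode-by-mode from the radial table
    (explicit DFT, no FFT), then convolved by a triple loop over voxel
    displacements.  Grids above 16^3 are refused.
    """
    if max(grid.dims) > 16:
        raise ValueError("direct convolution oracle limited to 16^3 grids")
    from .solvent import chi_on_grid

    c_fields = np.asarray(c_fields, float)
    n = solvent.n_sites
    N = grid.npoints
    dims = grid.dims
    kvec, k2 = kvectors(cell, grid, half=False)
    kmag = np.sqrt(k2)
    chi0 = solvent.chi_k0()
    chi_modes = chi_on_grid(solvent, kmag, chi0=chi0)   # (n, n, dims)
    chi_modes[:, :, 0, 0, 0] = chi0
    # explicit inverse DFT of each pair kernel: K(r_j) = (1/N) sum_m chi e^{ik r_j}
    frac = grid.fractional_coords().reshape(-1, 3)
    m1 = np.fft.fftfreq(dims[0]) * dims[0]
    m2 = np.fft.fftfreq(dims[1]) * dims[1]
    m3 = np.fft.fftfreq(dims[2]) * dims[2]
    M = np.stack(np.meshgrid(m1, m2, m3, indexing="ij"), axis=-1).reshape(-1, 3)
    phase = np.exp(2j * np.pi * (frac @ M.T))           # (N, N_modes)
    kern = np.empty((n, n, N))
    for a in range(n):
        for g in range(n):
            kern[a, g] = (phase @ chi_modes[a, g].reshape(-1)).real / N
    # triple loop over displacement: h(j) = sum_a sum_j' c_a(j') K_ag(j - j')
    idx = np.arange(N).reshape(dims)
    h = np.zeros((n, N))
    cflat = c_fields.reshape(n, N)
    # displacement indexing: build map from (j, j') to kernel voxel (j - j') mod dims
    coords = np.stack(np.meshgrid(*[np.arange(d) for d in dims],
                                  indexing="ij"), axis=-1).reshape(-1, 3)
    for jp in range(N):
        diff = (coords - coords[jp]) % np.array(dims)
        kidx = idx[diff[:, 0], diff[:, 1], diff[:, 2]]
        for g in range(n):
            for a in range(n):
                h[g] += cflat[a, jp] * kern[a, g][kidx]
    h = h.reshape((n,) + dims)
    if shift_values is not None:
        h += np.asarray(shift_values, float)[:, None, None, None]
    return h


def charging_quadrature_oracle(solute: Solute, solvent: BulkSolvent,
                               cell: UnitCell, grid: GridSpec,
                               closure="hnc", n_lambda: int = 24,
                               tolerance: float = 1e-9,
                               ewald: EwaldParams | None = None,
                               clamp_kt: float = 300.0,
                               power: int = 4) -> float:
    """Kirkwood charging route to the excess chemical potential along the
    linear path u(l) = l * u_PME (the background shift scales with l too):

        dmu = int_0^1 dl sum_g rho_g int u_PME_g(r) g_g(r; l) dr
              - kT sum_g rho_g h_bk_g int_0^1 dl int c~_g(r; l) dr .

    The second piece is the path term generated by the l-dependent
    background shift; it vanishes for neutral solutes and is accumulated
    from the oracle's own trajectory.  Gauss–Legendre quadrature after the
    substitution l = s**power, which clusters nodes at small l to resolve
    the boundary layer from the clamped repulsive cores (width ~ 1/beta
    u_max).  Each node warm-starts from the previous one.

    Validation oracle: one full 3D solve per node.  The closed form it
    checks must be evaluated on a state solved with the same ``clamp_kt``.
    """
    from .grid import integrate
    from .solver import BackgroundShift, background_shift, solve_3drism

    if ewald is None:
        rc = min(9.0, 0.5 * cell.min_width() * 0.999)
        ewald = EwaldParams(real_cutoff=rc)
    beta = solvent.beta
    u = site_potentials(solute, solvent.sites, cell, grid, ewald,
                        clamp=clamp_kt / beta).fields
    shift0 = background_shift(solvent, solute.net_charge, cell.volume)
    nodes, weights = np.polynomial.legendre.leggauss(n_lambda)
    s = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    lam_nodes = s ** power
    jac = power * s ** (power - 1)
    order = np.argsort(lam_nodes)

    rho = solvent.densities
    cfg = MDIISConfig(tolerance=tolerance, max_iterations=20000)
    c_warm = None
    total = 0.0
    path = 0.0
    for idx in order:
        lam = lam_nodes[idx]
        try:
            st = solve_3drism(solute, solvent, cell, grid, closure=closure,
                              mdiis_config=cfg, initial_c=c_warm, ewald=ewald,
                              u_fields=lam * u,
                              shift=BackgroundShift(lam * shift0.values),
                              t_cap=max(50.0, clamp_kt))
        except Exception as exc:
            raise RuntimeError(
                f"charging oracle: solve failed at lambda={lam:.6g}: {exc}"
            ) from exc
        c_warm = st.c_tilde
        wi = w[idx] * jac[idx]
        total += wi * sum(
            rho[g] * integrate(u[g] * (st.h[g] + 1.0), cell, grid)
            for g in range(solvent.n_sites))
        path += wi * sum(
            rho[g] * shift0.values[g] * integrate(st.c_tilde[g], cell, grid)
            for g in range(solvent.n_sites))
    return float(total - path / beta)


def wigner_shell_sum(max_radius: int = 30) -> float:
    """Loose real-space check of the Wigner constant (unit cube, k_e = 1):
    spherical lattice sum with uniform-background compensation plus a
    surface-deficit correction dQ/(2R) for the mismatch between the enclosed
    point-charge count and the background sphere.  Accurate to ~1e-2."""
    rng = np.arange(-max_radius - 1, max_radius + 2)
    N = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    r = np.sqrt((N * N).sum(axis=1))
    vals = []
    for R in (max_radius - 5.0, max_radius + 0.0):
        sel = (r > 0) & (r <= R)
        s = (1.0 / r[sel]).sum()
        dQ = (sel.sum() + 1) - (4.0 * np.pi / 3.0) * R ** 3
        E = 0.5 * s - np.pi * R * R - dQ / (2.0 * R)
        vals.append(-2.0 * E)
    return float(np.mean(vals))
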