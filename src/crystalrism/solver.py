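"""Self-consistent periodic 3D-RISM engine.

Each cycle applies the Ornstein–Zernike convolution in reciprocal space
(with the background shift h_bk for net-charged solutes), the closure in
real space, and an MDIIS update of the renormalized direct correlation
function c_tilde, until RMS(h_closure - h_OZ) falls below tolerance.

Background shift
----------------
SPME zeroes the k=0 electrostatic mode, which amounts to a uniform
neutralizing background charge -Q_solute/V_cell.  Folding the background
potential into c (giving c_tilde) moves its effect into a per-site constant

    h_bk_g = -4 pi beta k_e (Q_solute / V_cell)
             * lim_{k->0} sum_a q_a chi_hat[a, g](k) / k^2,

evaluated by Neville polynomial extrapolation of the radial susceptibility
at the smallest wavenumber nodes.  Adding h_bk to h_OZ each cycle makes the
converged solvent distribution exactly neutralize the solute charge.  It is
zero for neutral solutes and for ion-free solvents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .closures import ClosureSpec, closure_apply
from .constants import COULOMB
from .grid import GridSpec, SiteFieldSet, UnitCell, kvectors
from .mdiis import MDIIS, MDIISConfig
from .potential import EwaldParams, Solute, site_potentials
from .solvent import BulkSolvent, chi_on_grid, neville_extrapolate

__all__ = ["BackgroundShift", "RismState", "background_shift", "oz_apply",
           "solve_3drism", "RismConvergenceError"]


class RismConvergenceError(RuntimeError):
    def __init__(self, msg, state=None):
        super().__init__(msg)
        self.state = state


@dataclass(frozen=True)
class BackgroundShift:
    """Per-site constants h_bk_g compensating the PME neutralizing
    background; all zero when Q_solute = 0 or the solvent has no ions."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))

    def __getitem__(self, g):
        return self.values[g]

    @property
    def any(self) -> bool:
        return bool(np.any(self.values))


def background_shift(solvent: BulkSolvent, q_solute: float, v_cell: float,
                     m_nodes: int = 5) -> BackgroundShift:
    """Evaluate h_bk_g by Neville extrapolation of
    sum_a q_a chi_hat[a, g](k) / k^2 to k = 0 (in the k^2 variable).

    A convergence check compares the degree m-2 and m-1 extrapolants.
    """
    n = solvent.n_sites
    if q_solute == 0.0 or not solvent.has_ions:
        return BackgroundShift(np.zeros(n))
    q = solvent.charges
    k = solvent.k_grid[:m_nodes]
    x = k * k
    vals = np.zeros(n)
    for g in range(n):
        series = (q[:, None] * solvent.chi_hat[:, g, :m_nodes]).sum(axis=0) / x
        try:
            full, _ = neville_extrapolate(x, series)
            lower, _ = neville_extrapolate(x[:-1], series[:-1])
        except ArithmeticError as exc:
            raise ArithmeticError(
                f"background-shift extrapolation failed for site "
                f"{solvent.labels[g]}: {exc}"
            ) from exc
        if not np.isfinite(full):
            raise ArithmeticError(
                f"background-shift limit non-finite for site {solvent.labels[g]}"
            )
        scale = max(abs(full), 1e-12)
        if abs(full - lower) > 1e-3 * scale + 1e-10:
            raise ArithmeticError(
                f"background-shift extrapolation not converged for site "
                f"{solvent.labels[g]}: degree {m_nodes-1} -> {full:.6g}, "
                f"degree {m_nodes-2} -> {lower:.6g}"
            )
        vals[g] = full
    vals *= -4.0 * np.pi * solvent.beta * COULOMB * q_solute / v_cell
    return BackgroundShift(vals)


def oz_apply(c_fields: np.ndarray, chi3d: np.ndarray, chi0: np.ndarray,
             shift: BackgroundShift) -> np.ndarray:
    """h_OZ_g = sum_a c~_a * chi_ag (reciprocal-space product) + h_bk_g.

    ``chi3d`` holds chi_hat[a, g](|k|) on the rfftn mode layout; its k=0
    entry is ignored and replaced by the extrapolated ``chi0``.
    """
    c_fields = np.asarray(c_fields, float)
    if np.any(~np.isfinite(c_fields)):
        raise FloatingPointError("NaN/Inf in c~ fields entering OZ")
    n = c_fields.shape[0]
    dims = c_fields.shape[1:]
    c_hat = np.fft.rfftn(c_fields, axes=(1, 2, 3))
    h = np.empty_like(c_fields)
    # site-by-site accumulation keeps temporaries to one mode array
    for g in range(n):
        h_hat_g = c_hat[0] * chi3d[0, g]
        for a in range(1, n):
            h_hat_g += c_hat[a] * chi3d[a, g]
        h_hat_g[0, 0, 0] = c_hat[:, 0, 0, 0] @ chi0[:, g]
        h[g] = np.fft.irfftn(h_hat_g, s=dims, axes=(0, 1, 2))
    if shift.any:
        h += shift.values[:, None, None, None]
    return h


@dataclass
class RismState:
    """Converged (or best-effort) fields and iteration diagnostics."""

    c_tilde: np.ndarray           # (n_sites, dims) renormalized direct corr.
    h: np.ndarray                 # total correlation (closure branch)
    t: np.ndarray                 # closure exponent
    u_pme: np.ndarray             # per-site potential grids (kcal/mol)
    shift: BackgroundShift
    residuals: list
    iterations: int
    converged: bool
    tolerance: float
    solvent: BulkSolvent = None
    cell: UnitCell = None
    grid: GridSpec = None
    solute: Solute = None
    ewald: EwaldParams = None
    closure: ClosureSpec = None

    @property
    def g(self) -> np.ndarray:
        return self.h + 1.0

    @property
    def residual(self) -> float:
        return self.residuals[-1] if self.residuals else np.inf

    def site_fields(self, which: str = "g") -> SiteFieldSet:
        arr = {"g": self.g, "h": self.h, "c": self.c_tilde, "t": self.t,
               "u": self.u_pme}[which]
        return SiteFieldSet(np.asarray(arr), role=which,
                            site_labels=self.solvent.labels if self.solvent else [])


def solve_3drism(
    solute: Solute,
    solvent: BulkSolvent,
    cell: UnitCell,
    grid: GridSpec,
    closure: ClosureSpec | str = "kh",
    mdiis_config: MDIISConfig | None = None,
    initial_c: np.ndarray | None = None,
    ewald: EwaldParams | None = None,
    u_fields: np.ndarray | None = None,
    shift: BackgroundShift | None = None,
    clamp_kt: float = 500.0,
    t_cap: float = 50.0,
) -> RismState:
    """Run the periodic 3D-RISM cycle to self-consistency.

    ``initial_c`` warm-starts the iteration (default: uniformly zero).
    ``u_fields``/``shift`` override the internally built potential grids and
    background shift (used by the charging oracle, which scales both).
    """
    if isinstance(closure, str):
        closure = ClosureSpec.from_string(closure)
    if mdiis_config is None:
        mdiis_config = MDIISConfig()
    if ewald is None:
        rc = min(9.0, 0.5 * cell.min_width() * 0.999)
        ewald = EwaldParams(real_cutoff=rc)
    beta = solvent.beta
    n = solvent.n_sites

    if u_fields is None:
        u_fields = site_potentials(solute, solvent.sites, cell, grid, ewald,
                                   clamp=clamp_kt / beta).fields
    else:
        u_fields = np.asarray(u_fields, float)
    if shift is None:
        shift = background_shift(solvent, solute.net_charge, cell.volume)

    _, k2 = kvectors(cell, grid, half=True)
    kmag = np.sqrt(k2)
    chi0 = solvent.chi_k0()
    chi3d = chi_on_grid(solvent, kmag, chi0=chi0)

    shape = (n,) + grid.dims
    c = np.zeros(shape) if initial_c is None else np.array(initial_c, float).reshape(shape)
    acc = MDIIS(mdiis_config)
    residuals = []
    best = np.inf
    mbu = -beta * u_fields

    state = None
    for it in range(1, mdiis_config.max_iterations + 1):
        h_oz = oz_apply(c, chi3d, chi0, shift)
        t = mbu + h_oz - c
        h_cl = closure_apply(t, closure, t_cap=t_cap)
        dc = h_cl - h_oz
        rms = float(np.sqrt(np.mean(dc * dc)))
        residuals.append(rms)
        state = RismState(
            c_tilde=c, h=h_cl, t=t, u_pme=u_fields, shift=shift,
            residuals=residuals, iterations=it,
            converged=rms < mdiis_config.tolerance,
            tolerance=mdiis_config.tolerance,
            solvent=solvent, cell=cell, grid=grid, solute=solute,
            ewald=ewald, closure=closure,
        )
        if not np.isfinite(rms) or (rms > 1e4 * best and it > 20):
            raise RismConvergenceError(
                f"3D-RISM diverging at iteration {it} "
                f"(residual {rms:.3e}, best {best:.3e})", state=state)
        if rms < mdiis_config.tolerance:
            t_max = float(t.max())
            if t_max > t_cap - 2.0:
                raise RismConvergenceError(
                    f"converged solution sits at the transient exponent cap "
                    f"(max t = {t_max:.1f} vs cap {t_cap}); raise t_cap or "
                    f"use a PSE-n closure", state=state)
            return state
        best = min(best, rms)
        c = acc.step(c, dc).reshape(shape)
    raise RismConvergenceError(
        f"3D-RISM not converged in {mdiis_config.max_iterations} iterations "
        f"(final residual {residuals[-1]:.3e})", state=state)


def solvent_excess_charge(state: RismState) -> float:
    """sum_g q_g rho_g int h_g dr — equals -Q_solute at convergence for a
    charged solute in an ionic solvent (the electroneutrality property)."""
    from .grid import integrate

    total = 0.0
    for g, s in enumerate(state.solvent.sites):
        total += s.charge * s.density * integrate(state.h[g], state.cell, state.grid)
    return total
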