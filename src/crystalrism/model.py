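"""High-level modelling interface.

``PeriodicRISM`` bundles a periodic solute, a bulk solvent and the numerical
settings; ``fit()`` runs the self-consistent cycle and returns a
``PeriodicRISMResults`` carrying the converged fields, thermodynamic
observables, per-atom gradients and a ``summary()`` table.

Example
-------
>>> from crystalrism import fixtures, PeriodicRISM
>>> toy = fixtures.make_toy("cation_in_salt", seed=1)
>>> model = PeriodicRISM(toy.solute, toy.solvent(), toy.cell, spacing=0.5,
...                      closure="hnc")
>>> res = model.fit(tolerance=1e-6)
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .closures import ClosureSpec
from .grid import GridSpec, UnitCell, auto_grid
from .mdiis import MDIISConfig
from .potential import EwaldParams, Solute
from .solvent import BulkSolvent
from .solver import RismState, solve_3drism
from .thermo import (excess_chemical_potential, excess_numbers,
                     finite_difference_gradient, solvation_forces,
                     thermo_report)

__all__ = ["PeriodicRISM", "PeriodicRISMResults"]


class PeriodicRISM:
    """Periodic 3D-RISM model of the solvent around a fixed solute."""

    def __init__(self, solute: Solute, solvent: BulkSolvent, cell: UnitCell,
                 grid: GridSpec | None = None, spacing: float = 0.5,
                 closure: str | ClosureSpec = "kh",
                 ewald: EwaldParams | None = None):
        self.solute = solute
        self.solvent = solvent
        self.cell = cell
        self.grid = grid if grid is not None else auto_grid(cell, spacing)
        self.closure = (closure if isinstance(closure, ClosureSpec)
                        else ClosureSpec.from_string(closure))
        if ewald is None:
            rc = min(9.0, 0.5 * cell.min_width() * 0.999)
            ewald = EwaldParams(real_cutoff=rc)
        self.ewald = ewald

    def fit(self, tolerance: float = 1e-6, max_iterations: int = 10000,
            n_vectors: int = 5, damping: float = 0.7,
            initial_c: np.ndarray | None = None) -> "PeriodicRISMResults":
        cfg = MDIISConfig(n_vectors=n_vectors, damping=damping,
                          tolerance=tolerance, max_iterations=max_iterations)
        state = solve_3drism(self.solute, self.solvent, self.cell, self.grid,
                             closure=self.closure, mdiis_config=cfg,
                             initial_c=initial_c, ewald=self.ewald)
        return PeriodicRISMResults(self, state)


@dataclass
class PeriodicRISMResults:
    model: PeriodicRISM
    state: RismState

    @property
    def converged(self) -> bool:
        return self.state.converged

    @property
    def g(self) -> np.ndarray:
        """Per-site distribution functions g = h + 1 on the grid."""
        return self.state.g

    @property
    def delta_mu(self) -> float:
        return excess_chemical_potential(self.state)[0]

    @property
    def background_term(self) -> float:
        return excess_chemical_potential(self.state)[1]

    @property
    def excess_numbers(self) -> dict:
        return excess_numbers(self.state)

    def forces(self) -> np.ndarray:
        """Analytic gradients dDmu/dR_i (negate for MD forces)."""
        return solvation_forces(self.state, force_tolerance=self.state.tolerance)

    def finite_difference_forces(self, atoms=None, displacement=1e-4):
        return finite_difference_gradient(self.state, atoms=atoms,
                                          displacement=displacement)

    def report(self, forces: bool = False):
        return thermo_report(self.state, forces=forces)

    def summary(self) -> str:
        rep = self.report()
        rows = [
            ("closure", str(self.state.closure)),
            ("grid", "x".join(map(str, self.model.grid.dims))),
            ("iterations", self.state.iterations),
            ("residual RMS", f"{self.state.residual:.3e}"),
            ("solute charge (e)", f"{rep.solute_charge:+.4f}"),
            ("solvent excess charge (e)", f"{rep.solvent_excess_charge:+.4f}"),
            ("neutrality defect (e)", f"{rep.neutrality_defect:.2e}"),
            ("delta_mu (kcal/mol)", f"{rep.delta_mu:.4f}"),
            ("background term (kcal/mol)", f"{rep.background_term:.4f}"),
        ]
        df = pd.DataFrame(rows, columns=["quantity", "value"])
        ex = pd.DataFrame(
            [(k, f"{v:+.4f}") for k, v in rep.excess_numbers.items()],
            columns=["site", "excess number"])
        return ("Periodic 3D-RISM results\n"
                + df.to_string(index=False)
                + "\n\nExcess solvent numbers (per unit cell)\n"
                + ex.to_string(index=False))
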