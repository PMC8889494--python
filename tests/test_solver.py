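"""3D solver: background shift, OZ convolution vs the direct-space oracle,
MDIIS behaviour and full self-consistent solves on toy systems."""

import numpy as np
import pytest

from crystalrism.constants import COULOMB
from crystalrism.fixtures import (direct_convolution_oracle, ideal_gas_solvent,
                                  make_toy)
from crystalrism.grid import GridSpec, UnitCell, kvectors
from crystalrism.mdiis import MDIIS, MDIISConfig, mdiis_update
from crystalrism.solvent import BulkSolvent, SolventSite, SolventSpecies, chi_on_grid
from crystalrism.solver import (BackgroundShift, RismConvergenceError,
                                background_shift, oz_apply, solve_3drism,
                                solvent_excess_charge)


class TestBackgroundShift:
    def test_neutral_solute_zero(self, salt_solvent):
        s = background_shift(salt_solvent, 0.0, 1000.0)
        assert not s.any

    def test_ion_free_solvent_zero(self, water_solvent):
        s = background_shift(water_solvent, -3.0, 1000.0)
        assert s.values == pytest.approx(np.zeros(3))

    def test_synthetic_table_closed_form(self):
        """chi built so sum_a q_a chi_ag = A_g k^2 exactly: the extrapolated
        limit equals A_g and h_bk = -4 pi beta ke Q/V A_g."""
        k = 0.01 * np.arange(1, 2001)
        A = np.array([0.21, -0.37])
        q = np.array([1.0, -1.0])
        # chi_ag = q_a * (A_g k^2 + 0.5 k^4) / 2 => sum_a q_a chi_ag = A_g k^2 + ...
        chi = np.empty((2, 2, k.size))
        for a in range(2):
            for g in range(2):
                chi[a, g] = q[a] * (A[g] * k ** 2 - 0.04 * k ** 4) / 2.0
        species = [SolventSpecies.monatomic(SolventSite(f"S{i}", q[i], 0.1, 1.5, 1e-3))
                   for i in range(2)]
        sv = BulkSolvent(temperature=298.0, species=species, k_grid=k, chi_hat=chi)
        Q, V = 2.0, 1728.0
        out = background_shift(sv, Q, V)
        expect = -4.0 * np.pi * sv.beta * COULOMB * Q / V * A
        assert out.values == pytest.approx(expect, rel=1e-6)

    def test_divergent_extrapolation_raises(self):
        k = 0.01 * np.arange(1, 101)
        chi = np.empty((1, 1, k.size))
        chi[0, 0] = 1.0  # sum q chi / k^2 -> diverges as 1/k^2
        sv = BulkSolvent(
            temperature=298.0,
            species=[SolventSpecies.monatomic(SolventSite("I", 1.0, 0.1, 1.5, 1e-3))],
            k_grid=k, chi_hat=chi)
        with pytest.raises(ArithmeticError):
            background_shift(sv, 1.0, 1000.0)


class TestOZApply:
    def _small_problem(self, solvent, dims=(8, 8, 8), L=8.0):
        cell = UnitCell.cubic(L)
        grid = GridSpec(dims)
        _, k2 = kvectors(cell, grid)
        chi0 = solvent.chi_k0()
        chi3d = chi_on_grid(solvent, np.sqrt(k2), chi0=chi0)
        return cell, grid, chi3d, chi0

    def test_zero_in_zero_out(self, lj_solvent):
        cell, grid, chi3d, chi0 = self._small_problem(lj_solvent)
        h = oz_apply(np.zeros((1,) + grid.dims), chi3d, chi0,
                     BackgroundShift(np.zeros(1)))
        assert np.max(np.abs(h)) == 0.0

    def test_pure_shift(self, lj_solvent):
        cell, grid, chi3d, chi0 = self._small_problem(lj_solvent)
        h = oz_apply(np.zeros((1,) + grid.dims), chi3d, chi0,
                     BackgroundShift(np.array([0.37])))
        assert h == pytest.approx(np.full((1,) + grid.dims, 0.37))

    def test_nan_input_rejected(self, lj_solvent):
        cell, grid, chi3d, chi0 = self._small_problem(lj_solvent)
        c = np.zeros((1,) + grid.dims)
        c[0, 1, 2, 3] = np.nan
        with pytest.raises(FloatingPointError):
            oz_apply(c, chi3d, chi0, BackgroundShift(np.zeros(1)))

    def test_matches_direct_convolution_oracle(self, water_solvent, rng):
        """FFT convolution vs the O(N^2) direct-space triple loop on 8^3
        with the 3-site solvent."""
        cell = UnitCell.cubic(8.0)
        grid = GridSpec((8, 8, 8))
        _, k2 = kvectors(cell, grid)
        chi0 = water_solvent.chi_k0()
        chi3d = chi_on_grid(water_solvent, np.sqrt(k2), chi0=chi0)
        c = 0.3 * rng.standard_normal((3,) + grid.dims)
        shift = BackgroundShift(np.array([0.01, -0.02, 0.005]))
        h_fft = oz_apply(c, chi3d, chi0, shift)
        h_direct = direct_convolution_oracle(c, water_solvent, cell, grid,
                                             shift_values=shift.values)
        assert np.sqrt(np.mean((h_fft - h_direct) ** 2)) < 1e-8

    def test_oracle_refuses_large_grids(self, lj_solvent):
        with pytest.raises(ValueError, match="16"):
            direct_convolution_oracle(np.zeros((1, 24, 24, 24)), lj_solvent,
                                      UnitCell.cubic(12.0), GridSpec((24, 24, 24)))


class TestMDIIS:
    def test_single_entry_is_damped_picard(self, rng):
        x = rng.standard_normal(10)
        r = rng.standard_normal(10)
        cfg = MDIISConfig(damping=0.6)
        out = mdiis_update([x], [r], cfg)
        assert out == pytest.approx(x + 0.6 * r)

    def test_duplicate_entries_restart_not_crash(self, rng):
        x = rng.standard_normal(10)
        r = rng.standard_normal(10)
        acc = MDIIS(MDIISConfig(damping=0.5))
        acc.step(x, r)
        out = acc.step(x, r)  # identical entry: singular Gram matrix
        assert np.all(np.isfinite(out))

    def test_linear_problem_accelerated(self, rng):
        """On a linear fixed-point problem MDIIS converges in about the
        subspace dimension, far faster than damped Picard."""
        n = 12
        A = 0.6 * np.diag(rng.uniform(0.2, 1.0, n))
        b = rng.standard_normal(n)
        sol = np.linalg.solve(np.eye(n) - A, b)

        def residual(x):
            return A @ x + b - x

        cfg = MDIISConfig(n_vectors=n + 2, damping=0.5, tolerance=1e-12)
        acc = MDIIS(cfg)
        x = np.zeros(n)
        mdiis_iters = None
        for it in range(1, 200):
            r = residual(x)
            if np.sqrt(np.mean(r * r)) < 1e-10:
                mdiis_iters = it
                break
            x = acc.step(x, r)
        assert mdiis_iters is not None and mdiis_iters <= n + 3
        assert x == pytest.approx(sol)
        # Picard for comparison needs many more
        x = np.zeros(n)
        for pic_it in range(1, 200):
            r = residual(x)
            if np.sqrt(np.mean(r * r)) < 1e-10:
                break
            x = x + 0.5 * r
        assert pic_it > 3 * mdiis_iters

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MDIISConfig(n_vectors=0)
        with pytest.raises(ValueError):
            MDIISConfig(damping=1.5)


class TestSolve3D:
    def test_ideal_gas_analytic_fixed_point(self):
        """chi = identity: the converged distribution is exactly the
        Boltzmann factor of the potential, reached in one iteration."""
        toy = make_toy("ideal_gas_probe")
        sv = ideal_gas_solvent(density=0.01)
        grid = GridSpec((16, 16, 16))
        st = solve_3drism(toy.solute, sv, toy.cell, grid, closure="hnc",
                          mdiis_config=MDIISConfig(tolerance=1e-12))
        assert st.iterations <= 2
        gexact = np.exp(-sv.beta * st.u_pme[0])
        assert np.max(np.abs(st.g[0] - gexact)) < 1e-12

    def test_warm_start_converges_immediately(self, lj_solvent):
        toy = make_toy("lj_atom")
        grid = GridSpec((16, 16, 16))
        cfg = MDIISConfig(tolerance=1e-9)
        st = solve_3drism(toy.solute, lj_solvent, toy.cell, grid,
                          closure="hnc", mdiis_config=cfg)
        st2 = solve_3drism(toy.solute, lj_solvent, toy.cell, grid,
                           closure="hnc", mdiis_config=cfg,
                           initial_c=st.c_tilde)
        assert st2.iterations == 1

    def test_g_nonnegative(self, salt_solvent):
        toy = make_toy("cation_in_salt", seed=2)
        st = solve_3drism(toy.solute, salt_solvent, toy.cell,
                          GridSpec((16, 16, 16)), closure="kh",
                          mdiis_config=MDIISConfig(tolerance=1e-7))
        assert st.g.min() >= 0.0

    def test_neutrality_and_shift_regression(self, salt_solvent):
        """With the background shift the solvent neutralizes the solute;
        omitting the shift breaks neutrality by orders of magnitude."""
        toy = make_toy("cation_in_salt", seed=1)
        grid = GridSpec((24, 24, 24))
        cfg = MDIISConfig(tolerance=1e-8)
        st = solve_3drism(toy.solute, salt_solvent, toy.cell, grid,
                          closure="kh", mdiis_config=cfg)
        defect = abs(solvent_excess_charge(st) + toy.solute.net_charge)
        assert defect < 1e-3
        st_no = solve_3drism(toy.solute, salt_solvent, toy.cell, grid,
                             closure="kh", mdiis_config=cfg,
                             shift=BackgroundShift(np.zeros(5)))
        defect_no = abs(solvent_excess_charge(st_no) + toy.solute.net_charge)
        assert defect_no > 100.0 * max(defect, 1e-9)

    def test_neutral_solute_shift_free_equivalence(self, lj_solvent):
        """For a neutral solute the shifted and shift-free algorithms are
        the same algorithm (h_bk = 0 exactly)."""
        toy = make_toy("lj_atom")
        grid = GridSpec((16, 16, 16))
        cfg = MDIISConfig(tolerance=1e-10)
        st_a = solve_3drism(toy.solute, lj_solvent, toy.cell, grid,
                            closure="hnc", mdiis_config=cfg)
        st_b = solve_3drism(toy.solute, lj_solvent, toy.cell, grid,
                            closure="hnc", mdiis_config=cfg,
                            shift=BackgroundShift(np.zeros(1)))
        assert np.array_equal(st_a.h, st_b.h)

    def test_path_independence_of_mdiis_settings(self, lj_solvent):
        toy = make_toy("lj_atom")
        grid = GridSpec((16, 16, 16))
        st_a = solve_3drism(toy.solute, lj_solvent, toy.cell, grid,
                            closure="hnc",
                            mdiis_config=MDIISConfig(n_vectors=5, damping=0.7,
                                                     tolerance=1e-11))
        st_b = solve_3drism(toy.solute, lj_solvent, toy.cell, grid,
                            closure="hnc",
                            mdiis_config=MDIISConfig(n_vectors=10, damping=0.35,
                                                     tolerance=1e-11))
        assert np.max(np.abs(st_a.h - st_b.h)) < 1e-8

    def test_nonconvergence_carries_best_state(self, salt_solvent):
        toy = make_toy("cation_in_salt", seed=1)
        with pytest.raises(RismConvergenceError) as exc:
            solve_3drism(toy.solute, salt_solvent, toy.cell,
                         GridSpec((16, 16, 16)), closure="kh",
                         mdiis_config=MDIISConfig(tolerance=1e-12,
                                                  max_iterations=3))
        assert exc.value.state is not None
        assert exc.value.state.iterations == 3
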