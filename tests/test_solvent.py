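"""Bulk solvent stage: intramolecular matrix, radial transforms, the 1D
solver against independent oracles, susceptibility tables and file I/O."""

import numpy as np
import pytest

from crystalrism.closures import ClosureSpec, closure_apply
from crystalrism.constants import COULOMB, KBOLTZ
from crystalrism.fixtures import lj_species, water_like_species
from crystalrism.solvent import (BulkSolvent, RadialGrid, Rism1DError,
                                 SolventSite, SolventSpecies, chi_on_grid,
                                 intramolecular_matrix, neville_extrapolate,
                                 read_susceptibility_file, solve_rism1d,
                                 susceptibility, write_susceptibility_file,
                                 SusceptibilityFormatError)


class TestIntramolecularMatrix:
    def test_sinc_values(self):
        sp = water_like_species()[0]
        k = np.array([1e-6, np.pi, 2.0])
        w = intramolecular_matrix(sp, k)
        assert np.allclose(np.diagonal(w, axis1=0, axis2=1).T, 1.0)
        # O-H distance 1.0 Å: at k = pi the sinc has its first zero
        assert w[0, 1, 1] == pytest.approx(0.0, abs=1e-12)
        # k -> 0 limit
        assert w[0, 1, 0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.abs(w) <= 1.0 + 1e-12)
        assert w == pytest.approx(np.swapaxes(w, 0, 1))

    def test_invalid_geometry_rejected(self):
        s = SolventSite("A", 0.0, 0.1, 1.0, 0.01)
        with pytest.raises(ValueError, match="negative"):
            SolventSpecies((s, s), np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError, match="triangle"):
            s3 = (s, s, s)
            SolventSpecies(s3, np.array([[0, 1, 5.0], [1, 0, 1], [5.0, 1, 0]]))


class TestRadialTransforms:
    def test_round_trip(self, rng):
        grid = RadialGrid(0.05, 1024)
        f = np.exp(-0.3 * grid.r) * np.cos(grid.r)
        back = grid.ifbt(grid.fbt(f))
        assert np.max(np.abs(back - f)) < 1e-12 * np.max(np.abs(f))

    def test_analytic_yukawa_pair(self):
        """FT of exp(-a r)/r is 4 pi / (k^2 + a^2) (to the O(dr^2)
        quadrature error of the discrete transform)."""
        grid = RadialGrid(0.02, 4096)
        fh = grid.fbt(np.exp(-0.8 * grid.r) / grid.r)
        exact = 4 * np.pi / (grid.k ** 2 + 0.8 ** 2)
        sel = grid.k < 10.0
        assert np.max(np.abs(fh[sel] - exact[sel])) < 1e-3
        sel = grid.k < 1.0
        assert np.max(np.abs(fh[sel] - exact[sel]) / exact[sel]) < 1e-4


class TestRism1D:
    def test_ideal_gas_is_trivial(self):
        site = SolventSite("IG", 0.0, 0.0, 0.0, 0.01)
        sol = solve_rism1d([SolventSpecies.monatomic(site)], closure="hnc",
                           grid=RadialGrid(0.05, 512), tolerance=1e-12)
        assert np.max(np.abs(sol.h)) == 0.0
        assert np.max(np.abs(sol.c)) == 0.0

    def test_grid_must_be_power_of_two(self):
        with pytest.raises(ValueError, match="power of two"):
            solve_rism1d(lj_species(0.05), grid=RadialGrid(0.05, 1000))

    def test_low_density_lj_vs_picard_oracle(self):
        """Independent damped-Picard fixed-point iteration (no MDIIS, no
        Newton) must land on the same h(r)."""
        species = lj_species(0.05)
        grid = RadialGrid(0.05, 2048)
        sol = solve_rism1d(species, closure="hnc", grid=grid, tolerance=1e-10)

        site = species[0].sites[0]
        beta = 1.0 / (KBOLTZ * 298.0)
        r = grid.r
        x6 = (2.0 * site.lj_rmin_half / r) ** 6
        u = site.lj_epsilon * (x6 * x6 - 2.0 * x6)
        rho = site.density
        cs = np.zeros_like(r)
        for _ in range(4000):
            ch = grid.fbt(cs)
            hh = ch / (1.0 - rho * ch)
            ts = grid.ifbt(hh - ch)
            h = np.expm1(-beta * u + ts)
            res = (h - ts) - cs
            if np.sqrt(np.mean(res ** 2)) < 1e-12:
                break
            cs = cs + 0.5 * res
        assert np.sqrt(np.mean((sol.h[0, 0] - h) ** 2)) < 1e-6

    def test_virial_limit_at_vanishing_density(self):
        """rho*sigma^3 = 1e-4: h -> exp(-beta u) - 1 + O(rho)."""
        species = lj_species(1e-4)
        grid = RadialGrid(0.05, 2048)
        sol = solve_rism1d(species, closure="hnc", grid=grid, tolerance=1e-12)
        site = species[0].sites[0]
        beta = 1.0 / (KBOLTZ * 298.0)
        x6 = (2.0 * site.lj_rmin_half / grid.r) ** 6
        u = site.lj_epsilon * (x6 * x6 - 2.0 * x6)
        assert np.max(np.abs(sol.h[0, 0] - np.expm1(-beta * u))) < 1e-3

    def test_repulsive_core_depletion(self, lj_solvent):
        """For the neutral LJ fluid, g <= 1 inside the repulsive core."""
        # core region: r below ~0.8 * r_min where beta*u >> 1
        grid = RadialGrid(0.025, 8192)
        site = lj_solvent.sites[0]
        core = grid.r < 1.5 * site.lj_rmin_half
        h_core = lj_solvent.h_hat  # reciprocal; use real-space from solve
        sol = solve_rism1d(lj_species(0.4), closure="hnc", grid=grid,
                           tolerance=1e-10)
        assert np.all(sol.h[0, 0][core] <= 1e-10)

    def test_damping_path_independence(self):
        """Halving the warmup/MDIIS damping must not change the solution."""
        from crystalrism.mdiis import MDIISConfig

        grid = RadialGrid(0.05, 1024)
        sol_a = solve_rism1d(lj_species(0.3), grid=grid, tolerance=1e-11,
                             mdiis=MDIISConfig(damping=0.6, tolerance=1e-11))
        sol_b = solve_rism1d(lj_species(0.3), grid=grid, tolerance=1e-11,
                             mdiis=MDIISConfig(damping=0.3, tolerance=1e-11))
        assert np.max(np.abs(sol_a.h - sol_b.h)) < 1e-8

    def test_nonconvergence_raises_with_residual(self):
        with pytest.raises(Rism1DError) as exc:
            solve_rism1d(lj_species(0.9, eps=5.0), grid=RadialGrid(0.05, 512),
                         tolerance=1e-14, max_iter=2)
        assert exc.value.residual is None or np.isfinite(exc.value.residual)

    def test_drism_not_implemented(self):
        with pytest.raises(NotImplementedError):
            solve_rism1d(lj_species(0.3), drism=True)


class TestSusceptibility:
    def test_ideal_gas_chi_is_omega(self):
        site = SolventSite("IG", 0.0, 0.0, 0.0, 0.02)
        sol = solve_rism1d([SolventSpecies.monatomic(site)],
                           grid=RadialGrid(0.05, 512), tolerance=1e-12)
        sv = susceptibility(sol)
        assert sv.chi_hat[0, 0] == pytest.approx(np.ones(512))

    def test_monatomic_identity(self, lj_solvent):
        rho = lj_solvent.sites[0].density
        assert lj_solvent.chi_hat[0, 0] == pytest.approx(
            1.0 + rho * lj_solvent.h_hat[0, 0])

    def test_weighted_symmetry(self, salt_solvent):
        """rho_g * chi_ag == rho_a * chi_ga (the symmetric kernel that the
        chemical-potential derivation relies on)."""
        rho = salt_solvent.densities
        weighted = rho[None, :, None] * salt_solvent.chi_hat
        assert np.max(np.abs(weighted - np.swapaxes(weighted, 0, 1))) < 1e-10

    def test_water_oh_compressibility_route(self, water_solvent):
        """chi_OH(k->0) from Neville extrapolation must agree with the
        direct compressibility-route integral of h_OH(r)."""
        sol = solve_rism1d(water_like_species(), closure="kh",
                           grid=RadialGrid(0.025, 4096), tolerance=1e-12)
        grid = sol.grid
        rho = water_solvent.sites[0].density
        direct = 1.0 + rho * 4.0 * np.pi * np.trapezoid(
            grid.r ** 2 * sol.h[0, 1], grid.r)
        extrap = water_solvent.chi_k0()[0, 1]
        # omega_OH(0) = 1 for the rigid molecule
        assert extrap == pytest.approx(direct, rel=1e-3)


class TestSusceptibilityFile:
    def test_round_trip_bit_exact(self, tmp_path, water_solvent):
        path = tmp_path / "w.xvv"
        write_susceptibility_file(path, water_solvent)
        back = read_susceptibility_file(path)
        assert np.array_equal(back.chi_hat, water_solvent.chi_hat)
        assert back.temperature == water_solvent.temperature
        assert back.labels == water_solvent.labels

    def test_truncated_file_names_missing_part(self, tmp_path, water_solvent):
        path = tmp_path / "w.xvv"
        write_susceptibility_file(path, water_solvent)
        text = path.read_text().split("\n")
        (tmp_path / "trunc.xvv").write_text("\n".join(text[:30]))
        with pytest.raises(SusceptibilityFormatError, match="truncated|expected"):
            read_susceptibility_file(tmp_path / "trunc.xvv")

    def test_unknown_dialect_rejected(self, tmp_path):
        (tmp_path / "alien.xvv").write_text("SOMETHING-ELSE 9\n")
        with pytest.raises(SusceptibilityFormatError, match="dialect"):
            read_susceptibility_file(tmp_path / "alien.xvv")

    def test_site_count_mismatch(self, tmp_path, water_solvent):
        path = tmp_path / "w.xvv"
        write_susceptibility_file(path, water_solvent)
        bad = path.read_text().replace("chi nsites 3", "chi nsites 2")
        (tmp_path / "bad.xvv").write_text(bad)
        with pytest.raises(SusceptibilityFormatError, match="mismatch"):
            read_susceptibility_file(tmp_path / "bad.xvv")


class TestChiOnGrid:
    def test_node_values_and_tail(self, lj_solvent):
        k1 = lj_solvent.k_grid
        kmag = np.array([k1[10], k1[500], k1[-1] * 2.0])
        out = chi_on_grid(lj_solvent, kmag)
        assert out[0, 0, 0] == pytest.approx(lj_solvent.chi_hat[0, 0, 10])
        assert out[0, 0, 1] == pytest.approx(lj_solvent.chi_hat[0, 0, 500])
        # beyond k_max: rho*h part zero, monatomic omega = 1
        assert out[0, 0, 2] == pytest.approx(1.0)

    def test_ideal_gas_is_unity_everywhere(self, ideal_solvent, rng):
        kmag = rng.uniform(0.0, 50.0, (4, 4))
        out = chi_on_grid(ideal_solvent, kmag)
        assert out[0, 0] == pytest.approx(np.ones((4, 4)))

    def test_midpoint_matches_fine_table(self):
        """Downsample a 4x-denser radial table, interpolate back at the
        dropped nodes: the cubic interpolant must reproduce the true values
        to < 1e-6 relative."""
        fine = solve_rism1d(lj_species(0.3), grid=RadialGrid(0.05, 4096),
                            tolerance=1e-12)
        sv_f = susceptibility(fine)
        coarse = BulkSolvent(
            temperature=sv_f.temperature, species=sv_f.species,
            k_grid=sv_f.k_grid[3::4], chi_hat=sv_f.chi_hat[:, :, 3::4])
        # nodes absent from the coarse table, beyond the main structure
        # peak where chi curvature is largest (the cubic interpolant loses
        # ~2 digits of relative accuracy right at the peak)
        probe = slice(201, 2000, 4)
        out = chi_on_grid(coarse, sv_f.k_grid[probe])[0, 0]
        ref = sv_f.chi_hat[0, 0, probe]
        assert np.max(np.abs(out - ref) / np.abs(ref)) < 1e-6


class TestNeville:
    def test_polynomial_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 3.0 - 2.0 * x + 0.5 * x ** 2
        val, err = neville_extrapolate(x, y, 0.0)
        assert val == pytest.approx(3.0, abs=1e-12)

    def test_synthetic_chi_small_k_limit(self):
        """Toy susceptibility with closed-form small-k behaviour: the
        extrapolated sum_a q_a chi_ag / k^2 limit equals the constructed
        coefficient."""
        k = 0.01 * np.arange(1, 9)
        A = 0.3712
        series = A + 0.9 * k ** 2 - 0.2 * k ** 4
        val, err = neville_extrapolate(k ** 2, series)
        assert val == pytest.approx(A, rel=1e-9)

    def test_divergent_tableau_raises(self):
        x = np.array([1e-4, 2e-4, 3e-4, 4e-4, 5e-4, 6e-4])
        y = 1.0 / x  # diverges toward x=0
        with pytest.raises(ArithmeticError):
            neville_extrapolate(x, y)
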