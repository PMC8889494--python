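"""Periodic unit cell and the regular 3D grid covering it.

The grid is indexed along the lattice vectors (fractional coordinates), not
Cartesian axes, so triclinic cells are supported throughout.  Voxel centers
sit at fractional coordinates (i/n1, j/n2, k/n3) starting at the origin; the
cell is covered exactly once (periodic wrap, no duplicated endpoint).

FFT conventions used project-wide
---------------------------------
Continuous Fourier transforms on the cell are approximated as

    f_hat(k_m) ~= dV * FFT(f)[m],        f(r_j) = (N/V) * IFFT(f_hat)[j],

with numpy's unnormalized ``rfftn``/``irfftn``.  In particular a periodic
convolution ``h = c * chi`` with a kernel given by its *continuous* transform
``chi_hat`` is simply ``h = irfftn(rfftn(c) * chi_hat)`` — the dV and N/V
factors cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitCell",
    "GridSpec",
    "SiteFieldSet",
    "kvectors",
    "min_image_displacement",
    "integrate",
    "fft_friendly_size",
    "auto_grid",
]


@dataclass(frozen=True)
class UnitCell:
    """Periodic cell given by its lattice vectors (rows a, b, c, in Å)."""

    lattice: np.ndarray

    def __post_init__(self):
        lat = np.asarray(self.lattice, dtype=float)
        if lat.shape != (3, 3):
            raise ValueError("lattice must be a 3x3 matrix (rows a, b, c)")
        if np.linalg.det(lat) <= 0:
            raise ValueError("lattice must be right-handed (det > 0)")
        object.__setattr__(self, "lattice", lat)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.lattice))

    @property
    def inverse(self) -> np.ndarray:
        """Inverse lattice matrix; cart @ inverse = fractional."""
        return np.linalg.inv(self.lattice)

    @classmethod
    def cubic(cls, L: float) -> "UnitCell":
        return cls(np.eye(3) * float(L))

    @classmethod
    def from_parameters(cls, a, b, c, alpha=90.0, beta=90.0, gamma=90.0) -> "UnitCell":
        """Standard crystallographic convention: a along x, b in the xy plane."""
        al, be, ga = np.radians([alpha, beta, gamma])
        cx = c * np.cos(be)
        cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz2 = c * c - cx * cx - cy * cy
        if cz2 <= 0:
            raise ValueError("invalid cell parameters")
        lat = np.array(
            [
                [a, 0.0, 0.0],
                [b * np.cos(ga), b * np.sin(ga), 0.0],
                [cx, cy, np.sqrt(cz2)],
            ]
        )
        # clean tiny numerical noise for right angles
        lat[np.abs(lat) < 1e-10 * max(a, b, c)] = 0.0
        return cls(lat)

    def is_cubic(self, rtol: float = 1e-8) -> bool:
        lat = self.lattice
        L = lat[0, 0]
        return bool(np.allclose(lat, np.eye(3) * L, rtol=rtol, atol=1e-8 * max(L, 1.0)))

    def fractional(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, float) @ self.inverse

    def cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ self.lattice

    def min_width(self) -> float:
        """Smallest perpendicular width of the cell (bounds the usable cutoff)."""
        lat = self.lattice
        widths = []
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            n = np.cross(lat[j], lat[k])
            widths.append(abs(np.dot(lat[i], n)) / np.linalg.norm(n))
        return float(min(widths))


@dataclass(frozen=True)
class GridSpec:
    """Regular grid of dims (n1, n2, n3) points along the lattice vectors."""

    dims: tuple

    def __post_init__(self):
        dims = tuple(int(n) for n in self.dims)
        if len(dims) != 3 or any(n < 8 for n in dims):
            raise ValueError("grid needs three dims, each >= 8")
        object.__setattr__(self, "dims", dims)

    @property
    def npoints(self) -> int:
        n1, n2, n3 = self.dims
        return n1 * n2 * n3

    def spacing(self, cell: UnitCell) -> np.ndarray:
        """Per-axis spacing |a_i|/n_i in Å."""
        return np.linalg.norm(cell.lattice, axis=1) / np.array(self.dims)

    def voxel_volume(self, cell: UnitCell) -> float:
        return cell.volume / self.npoints

    def fractional_coords(self) -> np.ndarray:
        """(n1, n2, n3, 3) array of voxel-center fractional coordinates."""
        axes = [np.arange(n) / n for n in self.dims]
        f = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return f

    def cartesian_coords(self, cell: UnitCell) -> np.ndarray:
        return self.fractional_coords() @ cell.lattice


def fft_friendly_size(n: int) -> int:
    """Smallest integer >= n whose factors are all in {2, 3, 5, 7}."""
    n = max(int(n), 8)
    while True:
        m = n
        for p in (2, 3, 5, 7):
            while m % p == 0:
                m //= p
        if m == 1:
            return n
        n += 1


def auto_grid(cell: UnitCell, spacing: float = 0.5) -> GridSpec:
    """Smallest FFT-friendly grid with per-axis spacing <= ``spacing`` Å."""
    lengths = np.linalg.norm(cell.lattice, axis=1)
    dims = tuple(fft_friendly_size(int(np.ceil(L / spacing))) for L in lengths)
    return GridSpec(dims)


def kvectors(cell: UnitCell, grid: GridSpec, half: bool = True):
    """Reciprocal-lattice wavevectors for each FFT mode.

    Returns ``(kvec, k2)`` where ``kvec`` has shape dims(+half) x 3 and
    ``k2 = |k|**2``.  ``half=True`` matches ``rfftn`` output layout (last
    axis truncated).  k_m = 2*pi * m_signed @ inv(lattice).T (the rows of
    2*pi*inv(L).T are the reciprocal basis vectors, b_i . a_j = 2*pi d_ij);
    the k=0 mode is present exactly once at index (0,0,0).
    """
    n1, n2, n3 = grid.dims
    m1 = np.fft.fftfreq(n1) * n1
    m2 = np.fft.fftfreq(n2) * n2
    m3 = (np.fft.rfftfreq(n3) if half else np.fft.fftfreq(n3)) * n3
    M = np.stack(np.meshgrid(m1, m2, m3, indexing="ij"), axis=-1)
    kvec = 2.0 * np.pi * (M @ cell.inverse.T)
    k2 = np.einsum("...i,...i->...", kvec, kvec)
    return kvec, k2


def min_image_displacement(cell: UnitCell, r_a, r_b) -> np.ndarray:
    """Displacement r_b - r_a of minimal norm over the 27 neighbor images."""
    d = np.atleast_2d(np.asarray(r_b, float)) - np.atleast_2d(np.asarray(r_a, float))
    f = d @ cell.inverse
    f -= np.round(f)
    # nearest-fractional rounding can miss the optimum in skewed cells;
    # check the 27 surrounding translations explicitly
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], float
    )
    cand = (f[:, None, :] + shifts[None, :, :]) @ cell.lattice
    norms = np.einsum("abi,abi->ab", cand, cand)
    best = np.argmin(norms, axis=1)
    out = cand[np.arange(len(best)), best]
    if np.ndim(r_a) == 1 and np.ndim(r_b) == 1:
        return out[0]
    return out


def integrate(field: np.ndarray, cell: UnitCell, grid: GridSpec) -> float:
    """Mean-value quadrature: sum(field) * V_cell / N (exact for band-limited
    periodic integrands)."""
    field = np.asarray(field)
    if field.shape != grid.dims:
        raise ValueError(f"field shape {field.shape} does not match grid {grid.dims}")
    return float(field.sum() * grid.voxel_volume(cell))


@dataclass
class SiteFieldSet:
    """One real scalar grid field per solvent site, with a role tag."""

    fields: np.ndarray  # shape (n_sites, n1, n2, n3)
    role: str = ""
    site_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.fields = np.asarray(self.fields, float)
        if self.fields.ndim != 4:
            raise ValueError("fields must be (n_sites, n1, n2, n3)")

    @property
    def n_sites(self) -> int:
        return self.fields.shape[0]

    @property
    def dims(self) -> tuple:
        return self.fields.shape[1:]

    def __getitem__(self, i):
        return self.fields[i]
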