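"""Structure and parameter ingestion, volumetric map emission, reports.

Solute input routes
-------------------
* PQR (primary, self-contained): positions + per-atom charge + radius.  The
  PQR radius is taken as the LJ r_min/2; epsilons come from an optional
  side table (atom-name -> epsilon [, rmin/2 override]) since PQR carries
  none.  A CRYST1 record (or an explicit cell) supplies the lattice.
* PDB + Amber topology: coordinates and the unit cell from the PDB
  (CRYST1, altloc filtered by occupancy), charges and LJ parameters from a
  prmtop (text FLAG sections; minimal built-in parser).

Maps are written as OpenDX text or CCP4/MRC binary; both record the cell so
a voxel's fractional position is recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, UnitCell
from .potential import Solute, SoluteAtom

__all__ = [
    "read_solute", "read_pqr", "read_pdb", "read_prmtop", "read_lj_table",
    "write_map", "read_map", "write_dx", "read_dx", "write_mrc", "read_mrc",
    "write_warm_start", "read_warm_start",
    "report", "RunConfig", "DEFAULT_STRIP_RESIDUES",
]

WARM_START_VERSION = 1


def write_warm_start(path, c_tilde, grid: GridSpec):
    """Versioned binary dump of the renormalized direct correlation fields
    (numpy .npz with grid metadata) for warm-starting later solves."""
    np.savez(path, version=WARM_START_VERSION,
             dims=np.array(grid.dims), c_tilde=np.asarray(c_tilde))


def read_warm_start(path, grid: GridSpec):
    data = np.load(path)
    if int(data["version"]) != WARM_START_VERSION:
        raise ValueError(f"unsupported warm-start version {data['version']}")
    if tuple(data["dims"]) != grid.dims:
        raise ValueError(
            f"warm-start grid {tuple(data['dims'])} does not match {grid.dims}")
    return data["c_tilde"]

#: residue names removed by the solvent-stripping filter (user-extensible)
DEFAULT_STRIP_RESIDUES = frozenset({
    "HOH", "WAT", "TIP", "TIP3", "SPC", "DOD",
    "NA", "NA+", "K", "K+", "CL", "CL-", "MG", "CA", "ZN", "BR", "IOD",
})


# --------------------------------------------------------------------------
# solute readers
# --------------------------------------------------------------------------

def _cell_from_cryst1(line: str) -> UnitCell:
    a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
    al, be, ga = float(line[33:40]), float(line[40:47]), float(line[47:54])
    return UnitCell.from_parameters(a, b, c, al, be, ga)


def read_lj_table(path) -> dict:
    """Side table: lines of ``name epsilon [rmin_half]`` (kcal/mol, Å)."""
    table = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            name = parts[0]
            eps = float(parts[1])
            rmh = float(parts[2]) if len(parts) > 2 else None
            table[name] = (eps, rmh)
    return table


def read_pqr(path, lj_table=None, cell: UnitCell | None = None):
    """Read a PQR file -> (Solute, UnitCell or None).

    Whitespace-separated ATOM/HETATM records: serial name resname resid
    x y z charge radius.  Radius is used as LJ r_min/2; epsilon defaults to
    0 unless the side table provides it.
    """
    if isinstance(lj_table, (str, bytes)) or hasattr(lj_table, "__fspath__"):
        lj_table = read_lj_table(lj_table)
    lj_table = lj_table or {}
    atoms = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("CRYST1"):
                cell = _cell_from_cryst1(raw)
                continue
            if not raw.startswith(("ATOM", "HETATM")):
                continue
            parts = raw.split()
            # ATOM serial name resname [chain] resid x y z q r
            tail = parts[-5:]
            x, y, z, q, radius = (float(v) for v in tail)
            name = parts[2]
            eps, rmh_override = lj_table.get(name, (0.0, None))
            atoms.append(SoluteAtom((x, y, z), q, eps,
                                    rmh_override if rmh_override is not None
                                    else radius, name))
    return Solute(atoms), cell


def read_prmtop(path) -> dict:
    """Minimal Amber topology reader: per-atom charges (e) and LJ
    (epsilon kcal/mol, r_min/2 Å) only."""
    sections = {}
    name = None
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("%FLAG"):
                name = raw.split()[1]
                sections[name] = []
            elif raw.startswith("%"):
                continue
            elif name is not None:
                sections[name].extend(raw.split())
    def floats(key):
        return np.array([float(v) for v in sections[key]])
    def ints(key):
        return np.array([int(v) for v in sections[key]])

    try:
        charges = floats("CHARGE") / 18.2223  # Amber internal -> e
        ntypes = ints("POINTERS")[1]
        type_idx = ints("ATOM_TYPE_INDEX") - 1
        nb_idx = ints("NONBONDED_PARM_INDEX") - 1
        acoef = floats("LENNARD_JONES_ACOEF")
        bcoef = floats("LENNARD_JONES_BCOEF")
        names = sections.get("ATOM_NAME", [])
    except KeyError as exc:
        raise ValueError(f"prmtop missing required section: {exc}") from exc

    eps = np.zeros(len(type_idx))
    rmh = np.zeros(len(type_idx))
    for i, ti in enumerate(type_idx):
        j = nb_idx[ntypes * ti + ti]
        A, B = acoef[j], bcoef[j]
        if A > 0 and B > 0:
            eps[i] = B * B / (4.0 * A)
            rmh[i] = 0.5 * (2.0 * A / B) ** (1.0 / 6.0)
    return {"charges": charges, "lj_epsilon": eps, "lj_rmin_half": rmh,
            "names": list(names)}


def read_pdb(path, parameter_source=None, cell: UnitCell | None = None,
             strip_residues=DEFAULT_STRIP_RESIDUES):
    """Read a PDB via biotite: highest-occupancy altloc conformers kept,
    solvent/ion residues stripped, charges and LJ from an Amber topology.
    """
    import biotite.structure.io.pdb as pdbio

    pdb = pdbio.PDBFile.read(str(path))
    structure = pdb.get_structure(model=1, altloc="occupancy")
    if cell is None:
        with open(path) as fh:
            for raw in fh:
                if raw.startswith("CRYST1"):
                    cell = _cell_from_cryst1(raw)
                    break
    if cell is None:
        raise ValueError("PDB lacks CRYST1 and no cell was given")
    if parameter_source is None:
        raise ValueError(
            "PDB carries no charges/LJ; provide an Amber topology "
            "(parameter_source=...) or use a PQR file")
    params = (read_prmtop(parameter_source)
              if not isinstance(parameter_source, dict) else parameter_source)
    keep = ~np.isin(structure.res_name, list(strip_residues))
    if len(params["charges"]) != structure.array_length():
        # topology typically describes the stripped solute
        structure = structure[keep]
        if len(params["charges"]) != structure.array_length():
            raise ValueError(
                f"topology has {len(params['charges'])} atoms, PDB has "
                f"{structure.array_length()} after stripping")
    atoms = [
        SoluteAtom(tuple(structure.coord[i]), params["charges"][i],
                   params["lj_epsilon"][i], params["lj_rmin_half"][i],
                   structure.atom_name[i])
        for i in range(structure.array_length())
    ]
    return Solute(atoms), cell


def read_solute(path, format=None, parameter_source=None,
                cell: UnitCell | None = None, lj_table=None,
                strip_residues=DEFAULT_STRIP_RESIDUES):
    """Dispatch on format ('pqr' or 'pdb'; guessed from the suffix)."""
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt == "pqr":
        return read_pqr(path, lj_table=lj_table, cell=cell)
    if fmt == "pdb":
        return read_pdb(path, parameter_source=parameter_source, cell=cell,
                        strip_residues=strip_residues)
    raise ValueError(f"unsupported solute format {fmt!r}")


# --------------------------------------------------------------------------
# volumetric maps
# --------------------------------------------------------------------------

def write_dx(path, field_arr, cell: UnitCell, grid: GridSpec):
    """OpenDX scalar field; voxel (i,j,k) at fractional (i/n1, j/n2, k/n3)."""
    field_arr = np.asarray(field_arr)
    if field_arr.shape != grid.dims:
        raise ValueError("field shape does not match grid")
    n1, n2, n3 = grid.dims
    d = [cell.lattice[i] / grid.dims[i] for i in range(3)]
    lines = [
        f"object 1 class gridpositions counts {n1} {n2} {n3}",
        "origin 0.0 0.0 0.0",
        *(f"delta {v[0]:.10g} {v[1]:.10g} {v[2]:.10g}" for v in d),
        f"object 2 class gridconnections counts {n1} {n2} {n3}",
        f"object 3 class array type double rank 0 items {grid.npoints} data follows",
    ]
    flat = field_arr.reshape(-1)
    for i in range(0, flat.size, 3):
        lines.append(" ".join(np.format_float_scientific(v, precision=17)
                              for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "field" class field')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dx(path):
    """Read an OpenDX scalar field -> (array, UnitCell, GridSpec)."""
    deltas = []
    counts = None
    values = []
    n_items = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("object 1"):
                counts = tuple(int(v) for v in line.split()[-3:])
            elif line.startswith("delta"):
                deltas.append([float(v) for v in line.split()[1:4]])
            elif "data follows" in line:
                n_items = int(line.split("items")[1].split()[0])
            elif n_items is not None and len(values) < n_items and line \
                    and not line.startswith(("attribute", "object")):
                values.extend(float(v) for v in line.split())
    if counts is None or n_items is None:
        raise ValueError("malformed OpenDX file")
    grid = GridSpec(counts)
    lattice = np.array([np.array(deltas[i]) * counts[i] for i in range(3)])
    arr = np.array(values).reshape(counts)
    return arr, UnitCell(lattice), grid


_MRC_HEADER_SIZE = 1024


def write_mrc(path, field_arr, cell: UnitCell, grid: GridSpec):
    """Minimal CCP4/MRC 2014 writer (mode 2, float32), x fastest."""
    field_arr = np.asarray(field_arr, np.float32)
    if field_arr.shape != grid.dims:
        raise ValueError("field shape does not match grid")
    n1, n2, n3 = grid.dims
    lat = cell.lattice
    a, b, c = np.linalg.norm(lat, axis=1)
    def ang(u, v):
        return np.degrees(np.arccos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
    header = np.zeros(256, dtype="<i4")
    fheader = header.view("<f4")
    header[0:3] = (n1, n2, n3)          # NC, NR, NS with axes 1,2,3
    header[3] = 2                       # mode: float32
    header[7:10] = (n1, n2, n3)         # MX, MY, MZ
    fheader[10:13] = (a, b, c)
    fheader[13:16] = (ang(lat[1], lat[2]), ang(lat[0], lat[2]), ang(lat[0], lat[1]))
    header[16:19] = (1, 2, 3)           # MAPC/MAPR/MAPS
    fheader[19] = float(field_arr.min())
    fheader[20] = float(field_arr.max())
    fheader[21] = float(field_arr.mean())
    header[22] = 1                      # ISPG P1
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = 16708                  # little-endian machine stamp 0x4144
    fheader[54] = float(field_arr.std())
    with open(path, "wb") as fh:
        header.tofile(fh)
        # voxel (i,j,k): i (axis a) fastest
        field_arr.transpose(2, 1, 0).astype("<f4").tofile(fh)


def read_mrc(path):
    """Read back a (minimal) CCP4/MRC map -> (array, UnitCell, GridSpec)."""
    with open(path, "rb") as fh:
        header = np.fromfile(fh, dtype="<i4", count=256)
        fheader = header.view("<f4")
        nc, nr, ns = header[0:3]
        if header[3] != 2:
            raise ValueError("only mode-2 (float32) MRC supported")
        a, b, c = fheader[10:13]
        alpha, beta, gamma = fheader[13:16]
        data = np.fromfile(fh, dtype="<f4", count=nc * nr * ns)
    arr = data.reshape(ns, nr, nc).transpose(2, 1, 0)
    cell = UnitCell.from_parameters(a, b, c, alpha, beta, gamma)
    return arr.astype(np.float64), cell, GridSpec((int(nc), int(nr), int(ns)))


def write_map(path, field_arr, cell: UnitCell, grid: GridSpec, format="dx"):
    fmt = format.lower()
    if fmt in ("dx", "opendx"):
        write_dx(path, field_arr, cell, grid)
    elif fmt in ("mrc", "ccp4"):
        write_mrc(path, field_arr, cell, grid)
    else:
        raise ValueError(f"unsupported map format {format!r}")


def read_map(path, format=None):
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt in ("dx", "opendx"):
        return read_dx(path)
    if fmt in ("mrc", "ccp4", "map"):
        return read_mrc(path)
    raise ValueError(f"unsupported map format {format!r}")


# --------------------------------------------------------------------------
# run configuration and reports
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat run configuration; precedence CLI > config file > defaults."""

    solute: str = ""
    susceptibility: str = ""
    output_prefix: str = "rism"
    spacing: float = 0.5
    dims: tuple | None = None
    cell: tuple | None = None  # (a, b, c, alpha, beta, gamma), overrides CRYST1
    closure: str = "kh"
    tolerance: float = 1e-6
    max_iterations: int = 10000
    mdiis_vectors: int = 5
    mdiis_damping: float = 0.7
    real_cutoff: float = 9.0
    spline_order: int = 4
    dump_potentials: bool = False
    warm_start: str = ""
    seed: int = 0
    verbose: bool = False

    _TYPES = {
        "spacing": float, "tolerance": float, "mdiis_damping": float,
        "real_cutoff": float, "max_iterations": int, "mdiis_vectors": int,
        "spline_order": int, "seed": int,
        "dump_potentials": lambda v: v.lower() in ("1", "true", "yes"),
        "verbose": lambda v: v.lower() in ("1", "true", "yes"),
        "dims": lambda v: tuple(int(x) for x in v.replace(",", " ").split()),
        "cell": lambda v: tuple(float(x) for x in v.replace(",", " ").split()),
    }

    def unit_cell(self) -> "UnitCell | None":
        if self.cell is None:
            return None
        vals = list(self.cell) + [90.0] * (6 - len(self.cell))
        return UnitCell.from_parameters(*vals)

    @classmethod
    def from_file(cls, path, **overrides):
        """Flat ``key = value`` format, '#' comments."""
        values = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#")[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key not in cls.__dataclass_fields__:
                    raise ValueError(f"unknown config key {key!r}")
                conv = cls._TYPES.get(key, str)
                values[key] = conv(val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def report(thermo_report, run_config: RunConfig | None = None,
           sidecar_path=None) -> str:
    """Human-readable report + optional machine-readable JSON sidecar."""
    rep = thermo_report
    lines = [
        "# periodic 3D-RISM report (schema 1)",
        f"closure            : {rep.closure}",
        f"grid               : {'x'.join(map(str, rep.grid_dims))}",
        f"iterations         : {rep.iterations}",
        f"residual RMS       : {rep.residual:.3e}",
        f"solute charge      : {rep.solute_charge:+.6f} e",
        f"solvent excess q   : {rep.solvent_excess_charge:+.6f} e",
        f"neutrality defect  : {rep.neutrality_defect:.3e} e",
        f"delta_mu           : {rep.delta_mu:.6f} kcal/mol",
        f"background term    : {rep.background_term:.6f} kcal/mol",
        "excess numbers     :",
    ]
    for label, value in rep.excess_numbers.items():
        lines.append(f"    {label:<8s} {value:+.6f}")
    if run_config is not None:
        lines.append(f"config             : closure={run_config.closure} "
                     f"spacing={run_config.spacing} seed={run_config.seed}")
    text = "\n".join(lines)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(rep.to_dict(), fh, indent=1)
    return text
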