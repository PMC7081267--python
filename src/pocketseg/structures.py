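"""Molecular structures, volumetric maps and their file formats.

Proteins arrive as prepared mol2 or PDB files; reference pockets arrive as
mol2 point clouds (one dummy atom per cavity grid point).  Predicted
probability densities can be exported as Gaussian cube or HDF5 ``cmap``
volumes for inspection in molecular viewers, and predicted pocket-forming
residues as mol2 substructures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

#: Å → Bohr, CODATA value used by cube-file readers/writers.
BOHR_PER_ANGSTROM = 1.8897259886

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Mo", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn", "Sb", "Te", "I", "Xe",
    "Cs", "Ba", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi",
    "U", "Du",
}

class FormatError(ValueError):
    """A structure file could not be interpreted in the requested format."""


@dataclass
class AtomRecord:
    """One atom: identity, residue assignment, coordinates and charge."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    coords: np.ndarray
    partial_charge: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.element not in _ELEMENTS:
            raise ValueError(f"atom {self.serial}: unrecognized element {self.element!r}")


@dataclass
class MolecularStructure:
    """An ordered collection of atoms parsed from one file.

    Used both for proteins and for pocket point clouds (where each "atom" is
    a cavity grid point, conventionally typed ``Du``).
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    source_path: str = ""
    source_format: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            raise ValueError("atom serials must be unique within a structure")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coords for a in self.atoms])

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]

    def residues(self) -> set[tuple[str, int]]:
        return {(a.chain_id, a.residue_id) for a in self.atoms}


@dataclass
class VolumetricMap:
    """A scalar field on a regular cubic lattice.

    ``origin`` is the Cartesian position (Å) of grid node ``[0, 0, 0]``;
    node ``[i, j, k]`` sits at ``origin + spacing * (i, j, k)``.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D array")

    def validate_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volumetric map contains non-finite values")


# ---------------------------------------------------------------------------
# reading


def _element_from_mol2_type(atom_type: str, name: str) -> str:
    """SYBYL atom types are 'El' or 'El.sub' (C.3, N.ar, Du)."""
    sym = atom_type.split(".")[0].capitalize()
    if sym in _ELEMENTS:
        return sym
    # fall back to leading letters of the atom name
    lead = "".join(c for c in name if c.isalpha())[:2].capitalize()
    if lead in _ELEMENTS:
        return lead
    if lead[:1] in _ELEMENTS:
        return lead[:1]
    return "Du"


def _read_mol2(path: Path) -> MolecularStructure:
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise FormatError(f"no atoms parsed from {path} as mol2: {exc}") from exc
    atoms = []
    has_charges = hasattr(u.atoms, "charges")
    for i, a in enumerate(u.atoms):
        atoms.append(
            AtomRecord(
                serial=int(getattr(a, "id", i + 1)),
                name=str(a.name),
                element=_element_from_mol2_type(str(a.type), str(a.name)),
                residue_name=str(a.resname),
                residue_id=int(a.resid),
                chain_id="",
                coords=np.asarray(a.position, dtype=float),
                partial_charge=float(a.charge) if has_charges else 0.0,
            )
        )
    return MolecularStructure(atoms, str(path), "mol2")


def _read_pdb(path: Path) -> MolecularStructure:
    import biotite.structure.io.pdb as bpdb

    f = bpdb.PDBFile.read(str(path))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arr = f.get_structure(model=1, altloc="first", extra_fields=["atom_id", "charge"])
    except Exception as exc:
        raise FormatError(f"no atoms parsed from {path} as pdb: {exc}") from exc
    atoms = []
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).capitalize()
        if elem not in _ELEMENTS:
            elem = "Du"
        atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]),
                element=elem,
                residue_name=str(arr.res_name[i]),
                residue_id=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                coords=np.asarray(arr.coord[i], dtype=float),
                partial_charge=float(arr.charge[i]),
            )
        )
    return MolecularStructure(atoms, str(path), "pdb")


def read_structure(path: str | Path, format: str = "auto") -> MolecularStructure:
    """Read a protein structure or pocket point cloud.

    Parameters
    ----------
    path:
        mol2 or PDB file.
    format:
        ``"mol2"``, ``"pdb"`` or ``"auto"`` (infer from the extension).

    Hydrogens are retained in the records (the featurizer drops them); mol2
    partial charges are preserved, PDB formal charges default to 0.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"structure file not found: {path}")
    if format == "auto":
        ext = path.suffix.lower().lstrip(".")
        if ext in ("mol2", "ml2"):
            format = "mol2"
        elif ext in ("pdb", "ent"):
            format = "pdb"
        else:
            raise FormatError(f"cannot infer format from extension of {path}")
    if format == "mol2":
        structure = _read_mol2(path)
    elif format == "pdb":
        structure = _read_pdb(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(structure) == 0:
        raise FormatError(f"no atoms parsed from {path} as {format}")
    return structure


# ---------------------------------------------------------------------------
# writing


def write_mol2(structure: MolecularStructure, path: str | Path, mol_name: str = "pocketseg") -> None:
    """Write a structure as a TRIPOS mol2 file (atoms only, no bonds)."""
    lines = [
        "@<TRIPOS>MOLECULE",
        mol_name,
        f"{len(structure.atoms)} 0 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for a in structure.atoms:
        x, y, z = a.coords
        lines.append(
            f"{a.serial:>7d} {a.name:<8s} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
            f"{a.element:<6s} {a.residue_id:>4d} {a.residue_name:<8s} {a.partial_charge:>9.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_pocket_mol2(
    structure: MolecularStructure,
    residue_ids: Iterable[tuple[str, int]],
    path: str | Path,
) -> None:
    """Write the atoms of selected residues as a mol2 substructure.

    ``residue_ids`` is a set of ``(chain_id, residue_id)`` pairs, as produced
    by :func:`pocketseg.inference.pocket_residues`.  An empty selection is
    written as a 0-atom file with a warning.
    """
    wanted = set(residue_ids)
    unknown = wanted - structure.residues()
    if unknown:
        raise ValueError(f"residues not present in structure: {sorted(unknown)!r}")
    selected = [a for a in structure.atoms if (a.chain_id, a.residue_id) in wanted]
    if not selected:
        logger.warning("empty residue selection for %s: writing 0-atom mol2", path)
    write_mol2(MolecularStructure(selected), path, mol_name="pocket")


def write_cube(vmap: VolumetricMap, path: str | Path) -> None:
    """Write a Gaussian cube file.

    Uses the most widely parsed dialect: distances in Bohr with positive
    voxel counts, one dummy atom (the format requires at least one atom
    line), values in z-fastest order with 6 per line.
    """
    vmap.validate_finite()
    nx, ny, nz = vmap.values.shape
    b = BOHR_PER_ANGSTROM
    ox, oy, oz = vmap.origin * b
    step = vmap.spacing * b
    lines = [
        "pocketseg volumetric map",
        "pocket probability density",
        f"{1:>5d}{ox:>12.6f}{oy:>12.6f}{oz:>12.6f}",
        f"{nx:>5d}{step:>12.6f}{0.0:>12.6f}{0.0:>12.6f}",
        f"{ny:>5d}{0.0:>12.6f}{step:>12.6f}{0.0:>12.6f}",
        f"{nz:>5d}{0.0:>12.6f}{0.0:>12.6f}{step:>12.6f}",
        f"{1:>5d}{0.0:>12.6f}{ox:>12.6f}{oy:>12.6f}{oz:>12.6f}",
    ]
    out = []
    vals = vmap.values.reshape(nx * ny * nz)
    for start in range(0, vals.size, 6):
        out.append("".join(f"{v:>13.5E}" for v in vals[start : start + 6]))
    Path(path).write_text("\n".join(lines + out) + "\n")


def read_cube(path: str | Path) -> VolumetricMap:
    """Read a Gaussian cube file written by :func:`write_cube` (or compatible)."""
    text = Path(path).read_text().splitlines()
    natoms = int(text[2].split()[0])
    origin = np.array([float(v) for v in text[2].split()[1:4]]) / BOHR_PER_ANGSTROM
    counts, steps = [], []
    for line in text[3:6]:
        parts = line.split()
        counts.append(int(parts[0]))
        axis = np.array([float(v) for v in parts[1:4]])
        steps.append(np.linalg.norm(axis) / BOHR_PER_ANGSTROM)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise FormatError(f"anisotropic cube spacing in {path}")
    data_start = 6 + abs(natoms)
    vals = np.array([float(v) for line in text[data_start:] for v in line.split()])
    if vals.size != np.prod(counts):
        raise FormatError(f"cube data size mismatch in {path}")
    return VolumetricMap(origin, float(steps[0]), vals.reshape(counts))


def write_cmap(vmap: VolumetricMap, path: str | Path) -> None:
    """Write an HDF5 volumetric container ("cmap").

    Layout: group ``/map_0`` with dataset ``values`` (3D float32 preserved
    as given) and attributes ``origin`` and ``step`` in Å.  This is a
    minimal hierarchical-container mapping of the Chimera map vocabulary;
    round trips through :func:`read_cmap` are exact.
    """
    import h5py

    vmap.validate_finite()
    with h5py.File(path, "w") as f:
        g = f.create_group("map_0")
        g.create_dataset("values", data=vmap.values)
        g.attrs["origin"] = vmap.origin
        g.attrs["step"] = float(vmap.spacing)


def read_cmap(path: str | Path) -> VolumetricMap:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["map_0"]
        return VolumetricMap(np.array(g.attrs["origin"]), float(g.attrs["step"]), g["values"][()])
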