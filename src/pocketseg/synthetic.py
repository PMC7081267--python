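"""Desk-scale pseudo-proteins with planted surface cavities.

Real training data pairs prepared protein structures with cavity point
clouds.  At desk scale we emulate the geometry only: a "protein" is a ball
of atoms with one or more spherical cavities carved out near the surface,
and each cavity is described by a point cloud on a 2 Å lattice — the same
representation the real reference pockets use.  The cavity is a density
hole adjacent to the surface, which gives a learnable geometric signal for
training sanity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structures import AtomRecord, MolecularStructure, write_mol2
from .training import DatasetEntry, DatasetIndex

#: C-dominated element palette; every element class is exercised over seeds.
DEFAULT_ELEMENT_FREQUENCIES: dict[str, float] = {
    "C": 0.55, "N": 0.15, "O": 0.18, "S": 0.04, "P": 0.02,
    "F": 0.02, "Zn": 0.02, "Se": 0.01, "B": 0.01,
}

_ATOMS_PER_RESIDUE = 8


class GenerationError(RuntimeError):
    """The requested toy geometry could not be realized."""


@dataclass(frozen=True)
class ToyComplexSpec:
    seed: int = 0
    n_atoms: int = 400
    protein_radius: float = 18.0
    pocket_radius: float = 5.0
    n_pockets: int = 1
    element_frequencies: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_ELEMENT_FREQUENCIES.items()
    )

    def __post_init__(self) -> None:
        if self.pocket_radius >= self.protein_radius:
            raise ValueError("pocket_radius must be smaller than protein_radius")
        if self.n_atoms < 10:
            raise ValueError("n_atoms must be at least 10")


def _pocket_centers(spec: ToyComplexSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Cavity centers at distance R - r from the origin, pairwise disjoint."""
    dist = spec.protein_radius - spec.pocket_radius
    centers: list[np.ndarray] = []
    for _ in range(spec.n_pockets):
        for _attempt in range(1000):
            v = rng.normal(size=3)
            c = dist * v / np.linalg.norm(v)
            if all(np.linalg.norm(c - o) > 2 * spec.pocket_radius for o in centers):
                centers.append(c)
                break
        else:
            raise GenerationError(
                f"could not place {spec.n_pockets} non-overlapping pockets "
                f"of radius {spec.pocket_radius} after 1000 attempts"
            )
    return centers


def _pocket_cloud(center: np.ndarray, radius: float, lattice: float = 2.0) -> np.ndarray:
    """Points of a ``lattice``-spaced grid inside the cavity sphere."""
    k = int(np.floor(radius / lattice))
    axis = np.arange(-k, k + 1) * lattice
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + center
    return pts[np.linalg.norm(pts - center, axis=1) <= radius]


def make_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[MolecularStructure, list[MolecularStructure], str]:
    """Generate one pseudo-protein, its cavity point clouds and a group id.

    Atoms are rejection-sampled uniformly inside the protein ball,
    excluding the cavity spheres; each cavity is returned as a point cloud
    of dummy atoms on a 2 Å lattice.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _pocket_centers(spec, rng)

    elements, freqs = zip(*spec.element_frequencies)
    probs = np.asarray(freqs, dtype=float)
    probs = probs / probs.sum()

    coords: list[np.ndarray] = []
    while len(coords) < spec.n_atoms:
        p = rng.uniform(-spec.protein_radius, spec.protein_radius, size=3)
        if np.linalg.norm(p) > spec.protein_radius:
            continue
        if any(np.linalg.norm(p - c) <= spec.pocket_radius for c in centers):
            continue
        coords.append(p)

    atoms = []
    for i, p in enumerate(coords):
        elem = str(rng.choice(elements, p=probs))
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=f"{elem}{i + 1}",
                element=elem,
                residue_name="TOY",
                residue_id=i // _ATOMS_PER_RESIDUE + 1,
                chain_id="A",
                coords=p,
                partial_charge=float(np.round(rng.normal(0.0, 0.2), 4)),
            )
        )
    protein = MolecularStructure(atoms, source_format="generated")

    clouds = []
    for c in centers:
        pts = _pocket_cloud(c, spec.pocket_radius)
        cloud_atoms = [
            AtomRecord(
                serial=j + 1,
                name=f"Du{j + 1}",
                element="Du",
                residue_name="CAV",
                residue_id=1,
                chain_id="A",
                coords=pt,
            )
            for j, pt in enumerate(pts)
        ]
        clouds.append(MolecularStructure(cloud_atoms, source_format="generated"))
    group_id = f"toy{spec.seed:05d}"
    return protein, clouds, group_id


def make_learnable_dataset(
    n: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
    base_spec: ToyComplexSpec = ToyComplexSpec(),
) -> tuple[DatasetIndex, list[tuple[MolecularStructure, list[MolecularStructure]]]]:
    """Generate ``n`` toy complexes with distinct group ids.

    When ``out_dir`` is given, mol2 files and a ``manifest.tsv`` are
    written there (paths in the manifest are relative to it); the returned
    index then references those files.  The in-memory structures are
    returned either way.
    """
    entries: list[DatasetEntry] = []
    complexes = []
    for i in range(n):
        spec = ToyComplexSpec(
            seed=seed * 10_000 + i,
            n_atoms=base_spec.n_atoms,
            protein_radius=base_spec.protein_radius,
            pocket_radius=base_spec.pocket_radius,
            n_pockets=base_spec.n_pockets,
            element_frequencies=base_spec.element_frequencies,
        )
        protein, clouds, group = make_toy_complex(spec)
        complexes.append((protein, clouds))
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            ppath = out / f"protein_{i:03d}.mol2"
            write_mol2(protein, ppath, mol_name=group)
            cpaths = []
            for j, cloud in enumerate(clouds):
                cpath = out / f"pocket_{i:03d}_{j}.mol2"
                write_mol2(cloud, cpath, mol_name=f"{group}_cavity{j}")
                cpaths.append(str(cpath))
            entries.append(DatasetEntry(str(ppath), cpaths, group))
    index = DatasetIndex(entries)
    if out_dir is not None:
        index.to_manifest(Path(out_dir) / "manifest.tsv")
    return index, complexes
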