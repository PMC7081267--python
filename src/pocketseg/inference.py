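"""Prediction and post-processing: density → discrete pockets → residues.

A structure is featurized onto a lattice centered on its heavy-atom
center, passed through the network, and the resulting probability density
is binarized (threshold 0.5 by default) and split into face-connected
components.  Small components are discarded; survivors become ranked
pocket segments from which pocket-forming residues and export files are
derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .features import featurize_atoms
from .grid import GridSpec, make_grid, protein_center
from .nn import UNet3D
from .structures import MolecularStructure, VolumetricMap, write_cmap, write_cube, write_pocket_mol2

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_VOXELS = 50  # 400 Å³ at 2 Å spacing
DEFAULT_RESIDUE_CUTOFF = 4.5


@dataclass
class Density:
    """Predicted per-voxel pocket probability on a known lattice."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("density must be a 3D array")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("density values must lie in [0, 1]")

    def to_map(self) -> VolumetricMap:
        return VolumetricMap(self.spec.origin, self.spec.spacing, self.values)


@dataclass
class PocketSegment:
    """One extracted pocket: its voxels, confidence score and center."""

    voxel_indices: np.ndarray  # (n, 3) int lattice indices
    score: float  # Σ probability over member voxels
    center: np.ndarray  # unweighted centroid of member voxel centers, Å
    spec: GridSpec

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    @property
    def volume(self) -> float:
        """Å³ (voxel count × spacing³)."""
        return self.n_voxels * self.spec.spacing**3

    def mask(self) -> np.ndarray:
        p = self.spec.points_per_axis
        m = np.zeros((p, p, p), dtype=np.uint8)
        idx = self.voxel_indices
        m[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        return m


def predict_density(
    model: UNet3D, structure: MolecularStructure, grid_spec_template: GridSpec = GridSpec()
) -> Density:
    """Featurize, voxelize (lattice centered on the protein center) and predict."""
    if not len(structure):
        raise ValueError("cannot predict for an empty structure")
    spec = GridSpec(
        center=tuple(protein_center(structure)),
        spacing=grid_spec_template.spacing,
        points_per_axis=grid_spec_template.points_per_axis,
    )
    grid = make_grid(featurize_atoms(structure), spec)
    y = model.forward(grid.values[None])[0, ..., 0]
    return Density(spec, np.clip(y.astype(np.float64), 0.0, 1.0))


def binarize(density: Density | np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary mask: 1 where probability >= threshold."""
    values = density.values if isinstance(density, Density) else np.asarray(density)
    return (values >= threshold).astype(np.uint8)


def extract_pockets(
    density: Density,
    threshold: float = DEFAULT_THRESHOLD,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> list[PocketSegment]:
    """Split the binarized density into pocket segments, best first.

    Components are found under 6-connectivity (face adjacency); components
    with fewer than ``min_voxels`` voxels are discarded; the score of a
    segment is the summed probability over its voxels.  Closely spaced
    pockets may merge into one component — splitting merged pockets at
    local probability maxima is intentionally not attempted.
    """
    binary = binarize(density, threshold)
    structure6 = ndimage.generate_binary_structure(3, 1)  # faces only
    labels, n = ndimage.label(binary, structure=structure6)
    segments: list[PocketSegment] = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_voxels:
            continue
        score = float(density.values[idx[:, 0], idx[:, 1], idx[:, 2]].sum())
        center = density.spec.node_coords(idx).mean(axis=0)
        segments.append(PocketSegment(idx, score, center, density.spec))
    segments.sort(key=lambda s: -s.score)
    return segments


def segment_center(segment: PocketSegment, probability_weighted: bool = False, density: Density | None = None) -> np.ndarray:
    """Segment center; optionally probability-weighted (needs the density)."""
    if not probability_weighted:
        return segment.center
    if density is None:
        raise ValueError("probability-weighted center requires the density")
    idx = segment.voxel_indices
    w = density.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return (segment.spec.node_coords(idx) * w[:, None]).sum(axis=0) / w.sum()


def pocket_residues(
    structure: MolecularStructure,
    segment: PocketSegment,
    cutoff: float = DEFAULT_RESIDUE_CUTOFF,
) -> set[tuple[str, int]]:
    """Residues with any heavy atom within ``cutoff`` Å of a member voxel center."""
    heavy = structure.heavy_atoms()
    if not heavy:
        return set()
    voxel_centers = segment.spec.node_coords(segment.voxel_indices)
    tree = cKDTree(voxel_centers)
    dists, _ = tree.query(np.stack([a.coords for a in heavy]))
    return {(a.chain_id, a.residue_id) for a, d in zip(heavy, dists) if d <= cutoff}


def export_prediction(
    density: Density,
    segments: list[PocketSegment],
    structure: MolecularStructure,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("cube", "cmap", "mol2"),
    residue_cutoff: float = DEFAULT_RESIDUE_CUTOFF,
) -> list[Path]:
    """Write the density (cube/cmap) and one mol2 of residues per segment.

    mol2 files are named by rank: ``pocket0.mol2`` is the highest-scoring
    segment.  Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    vmap = density.to_map()
    if "cube" in formats:
        p = out_dir / "density.cube"
        write_cube(vmap, p)
        written.append(p)
    if "cmap" in formats:
        p = out_dir / "density.cmap"
        write_cmap(vmap, p)
        written.append(p)
    if "mol2" in formats:
        for rank, seg in enumerate(segments):
            p = out_dir / f"pocket{rank}.mol2"
            write_pocket_mol2(structure, pocket_residues(structure, seg, residue_cutoff), p)
            written.append(p)
    return written
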