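"""Voxel lattice: grid specification, voxelization, masks and augmentation.

The working representation is a cubic lattice of (by default) 36 nodes per
axis at 2 Å spacing, i.e. a 70 Å node-to-node span, centered on the protein
center.  Atoms are assigned to their nearest lattice node; pocket point
clouds become binary masks on the same lattice.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .structures import MolecularStructure

logger = logging.getLogger(__name__)

N_CHANNELS = 18


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the voxel lattice.

    Node ``i`` (per axis) lies at ``center - spacing*(points_per_axis-1)/2
    + spacing*i``; the default spec spans 70 Å node-to-node per axis.
    """

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: float = 2.0
    points_per_axis: int = 36

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.points_per_axis < 2:
            raise ValueError("points_per_axis must be at least 2")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def origin(self) -> np.ndarray:
        """Cartesian position (Å) of node (0, 0, 0)."""
        half = self.spacing * (self.points_per_axis - 1) / 2.0
        return np.asarray(self.center, dtype=float) - half

    @property
    def span(self) -> float:
        """Node-to-node extent per axis, Å."""
        return self.spacing * (self.points_per_axis - 1)

    def node_coords(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian coordinates (Å) of lattice nodes given (n, 3) indices."""
        return self.origin + self.spacing * np.asarray(indices, dtype=float)

    def point_to_index(self, coords: np.ndarray) -> np.ndarray:
        """Nearest-node index per axis, half-up tie-breaking; may be out of range."""
        rel = (np.atleast_2d(coords) - self.origin) / self.spacing
        return np.floor(rel + 0.5).astype(int)


@dataclass
class InputGrid:
    """Featurized protein voxel grid: spatial dims × 18 channels."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        p = self.spec.points_per_axis
        if self.values.shape != (p, p, p, N_CHANNELS):
            raise ValueError(
                f"expected grid of shape ({p},{p},{p},{N_CHANNELS}), got {self.values.shape}"
            )


@dataclass
class PocketMask:
    """Binary ground-truth segmentation on the same lattice as its InputGrid."""

    spec: GridSpec
    values: np.ndarray
    empty: bool = field(default=False)

    def __post_init__(self) -> None:
        p = self.spec.points_per_axis
        if self.values.shape != (p, p, p):
            raise ValueError(f"mask shape {self.values.shape} != lattice {(p, p, p)}")
        self.values = self.values.astype(np.uint8)
        self.empty = not bool(self.values.any())


def protein_center(structure: MolecularStructure) -> np.ndarray:
    """Unweighted mean of heavy-atom coordinates, Å."""
    heavy = structure.heavy_atoms()
    if not heavy:
        raise ValueError("structure has no heavy atoms")
    return np.mean([a.coords for a in heavy], axis=0)


def make_grid(featurized: list[tuple[np.ndarray, np.ndarray]], spec: GridSpec) -> InputGrid:
    """Scatter per-atom feature vectors onto the lattice.

    Each atom goes to its nearest node (half-up per axis); atoms landing
    outside the lattice are dropped; feature vectors of atoms sharing a node
    are summed channel-wise, so channel totals are conserved for retained
    atoms.
    """
    p = spec.points_per_axis
    values = np.zeros((p, p, p, N_CHANNELS), dtype=np.float32)
    if featurized:
        coords = np.stack([c for c, _ in featurized])
        feats = np.stack([f for _, f in featurized]).astype(np.float32)
        idx = spec.point_to_index(coords)
        inside = np.all((idx >= 0) & (idx < p), axis=1)
        n_dropped = int((~inside).sum())
        if n_dropped:
            logger.debug("make_grid: dropped %d atoms outside the lattice", n_dropped)
        idx = idx[inside]
        np.add.at(values, (idx[:, 0], idx[:, 1], idx[:, 2]), feats[inside])
    return InputGrid(spec, values)


def make_pocket_mask(pocket_points: MolecularStructure, spec: GridSpec) -> PocketMask:
    """Binary mask: 1 at every voxel cell containing at least one pocket point.

    A voxel cell is the ``spacing``-sized cube centered on a lattice node, so
    cell membership is nearest-node assignment with the same half-up
    tie-break as :func:`make_grid`.  Empty point clouds (or clouds entirely
    outside the lattice) yield an all-zero mask flagged ``empty``.
    """
    p = spec.points_per_axis
    values = np.zeros((p, p, p), dtype=np.uint8)
    if len(pocket_points):
        idx = spec.point_to_index(pocket_points.coords)
        inside = np.all((idx >= 0) & (idx < p), axis=1)
        idx = idx[inside]
        values[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return PocketMask(spec, values)


# ---------------------------------------------------------------------------
# augmentation: the 24 proper rotations of the cube + integer translations


def _proper_rotations() -> list[tuple[tuple[int, int, int], tuple[bool, bool, bool]]]:
    """Deterministic enumeration of the 24 proper axis-aligned rotations.

    Each element is an axis permutation plus per-axis flips whose combined
    parity is even (det = +1).  Applied to a cubic array, transpose+flip is
    an exact on-lattice rotation about the array center.
    """
    rots = []
    for perm in itertools.permutations(range(3)):
        perm_parity = 1
        for i in range(3):
            for j in range(i + 1, 3):
                if perm[i] > perm[j]:
                    perm_parity *= -1
        for flips in itertools.product((False, True), repeat=3):
            flip_parity = (-1) ** sum(flips)
            if perm_parity * flip_parity == 1:
                rots.append((perm, flips))
    assert len(rots) == 24
    return rots


ROTATIONS = _proper_rotations()


def rotation_matrix(rotation_id: int) -> np.ndarray:
    """3×3 signed-permutation matrix of rotation ``rotation_id`` (0–23)."""
    perm, flips = ROTATIONS[rotation_id]
    mat = np.zeros((3, 3), dtype=int)
    for new_ax in range(3):
        mat[new_ax, perm[new_ax]] = -1 if flips[new_ax] else 1
    return mat


def _rotate_array(a: np.ndarray, rotation_id: int) -> np.ndarray:
    perm, flips = ROTATIONS[rotation_id]
    axes = tuple(perm) + tuple(range(3, a.ndim))
    b = np.transpose(a, axes)
    for ax, f in enumerate(flips):
        if f:
            b = np.flip(b, axis=ax)
    return b


def _shift_array(a: np.ndarray, t: tuple[int, int, int]) -> np.ndarray:
    """Integer voxel shift along the 3 spatial axes, zero-filling vacated voxels."""
    out = np.zeros_like(a)
    src, dst = [], []
    n = a.shape[:3]
    for ax in range(3):
        ti = int(t[ax])
        if abs(ti) >= n[ax]:
            return out
        if ti >= 0:
            src.append(slice(0, n[ax] - ti))
            dst.append(slice(ti, n[ax]))
        else:
            src.append(slice(-ti, n[ax]))
            dst.append(slice(0, n[ax] + ti))
    out[tuple(dst)] = a[tuple(src)]
    return out


def augment(
    grid: InputGrid,
    mask: PocketMask,
    rotation_id: int,
    translation: tuple[int, int, int] = (0, 0, 0),
    max_translation: int = 3,
) -> tuple[InputGrid, PocketMask]:
    """Apply one of the 24 proper cube rotations plus an integer-voxel shift.

    The same transform is applied to grid and mask, preserving their
    co-registration; vacated voxels are zero-filled.  The translation cap
    (default 3 voxels = 6 Å at default spacing) matches the training
    augmentation policy.
    """
    if not 0 <= rotation_id < 24:
        raise ValueError(f"rotation_id must be in [0, 24), got {rotation_id}")
    translation = tuple(int(v) for v in translation)
    if any(abs(v) > max_translation for v in translation):
        raise ValueError(f"|translation| components must be <= {max_translation}")
    g = _shift_array(_rotate_array(grid.values, rotation_id), translation)
    m = _shift_array(_rotate_array(mask.values, rotation_id), translation)
    return InputGrid(grid.spec, np.ascontiguousarray(g)), PocketMask(mask.spec, np.ascontiguousarray(m))
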