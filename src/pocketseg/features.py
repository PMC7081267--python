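"""Per-atom chemical featurization: the 18-channel atomic description.

Each heavy atom is described by 18 real channels:

======  =======================================================
index   channel
======  =======================================================
0–8     element one-hot: B, C, N, O, P, S, Se, halogen, metal
9       hybridization (1 = sp, 2 = sp2, 3 = sp3)
10      heavy-atom bond count
11      heteroatom (non C/H) bond count
12      hydrophobic (binary)
13      aromatic (binary)
14      H-bond acceptor (binary)
15      H-bond donor (binary)
16      ring member (binary)
17      partial charge (e)
======  =======================================================

Input structures carry no bond records (prepared proteins and dummy-atom
point clouds), so perception is rule-based and geometric: bonds from
covalent-radius distance criteria, rings from graph cycles, aromaticity
from planar 5/6-membered C/N/O/S rings, donors from explicit-hydrogen
neighbors.  Unclassifiable elements get an all-zero element block but keep
the remaining channels.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .grid import N_CHANNELS
from .structures import MolecularStructure

logger = logging.getLogger(__name__)

ELEMENT_CLASSES = ("B", "C", "N", "O", "P", "S", "Se", "halogen", "metal")
HALOGENS = frozenset({"F", "Cl", "Br", "I"})
METALS = frozenset(
    {"Na", "K", "Ca", "Mg", "Mn", "Zn", "Fe", "Co", "Ni", "Cu", "Cd", "Hg",
     "Li", "Al", "Sr", "Ba", "Mo", "W", "Ag", "Au", "Pt", "Pd", "Tl", "Pb", "U"}
)

CHANNEL_NAMES = ELEMENT_CLASSES + (
    "hybridization", "heavy_degree", "hetero_degree",
    "hydrophobic", "aromatic", "acceptor", "donor", "ring", "partial_charge",
)

# covalent radii (Å); pairs within 1.3 * (r_i + r_j) are considered bonded
_COVALENT_RADIUS = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Se": 1.20, "Br": 1.20, "I": 1.39,
}
_DEFAULT_RADIUS = 1.4
_BOND_TOLERANCE = 1.3


def _element_class(element: str) -> int | None:
    if element in HALOGENS:
        return ELEMENT_CLASSES.index("halogen")
    if element in METALS:
        return ELEMENT_CLASSES.index("metal")
    if element in ELEMENT_CLASSES:
        return ELEMENT_CLASSES.index(element)
    return None


def _bond_pairs(elements: list[str], coords: np.ndarray) -> list[tuple[int, int]]:
    """Distance-criterion bonds: d(i, j) <= 1.3 * (r_cov_i + r_cov_j)."""
    if len(elements) < 2:
        return []
    radii = np.array([_COVALENT_RADIUS.get(e, _DEFAULT_RADIUS) for e in elements])
    tree = cKDTree(coords)
    max_cut = _BOND_TOLERANCE * 2 * radii.max()
    pairs = []
    for i, j in tree.query_pairs(max_cut):
        if np.linalg.norm(coords[i] - coords[j]) <= _BOND_TOLERANCE * (radii[i] + radii[j]):
            pairs.append((i, j))
    return pairs


def _ring_memberships(n: int, heavy_pairs: list[tuple[int, int]]) -> list[list[int]]:
    """Cycles of the heavy-atom bond graph (cycle basis)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(heavy_pairs)
    return nx.cycle_basis(g)


def _is_planar(coords: np.ndarray, tol: float = 0.15) -> bool:
    """RMS out-of-plane deviation of a point set below ``tol`` Å."""
    centered = coords - coords.mean(axis=0)
    if len(centered) < 4:
        return True
    sv = np.linalg.svd(centered, compute_uv=False)
    return float(sv[-1]) / np.sqrt(len(centered)) < tol


def featurize_atoms(structure: MolecularStructure) -> list[tuple[np.ndarray, np.ndarray]]:
    """Featurize every heavy atom of a structure.

    Returns a list of ``(coords, feature_vector)`` pairs, one per heavy
    atom, in input order.  Hydrogens are excluded from the output but their
    positions inform donor perception and hybridization.
    """
    if not len(structure):
        raise ValueError("cannot featurize an empty structure")
    atoms = structure.atoms
    elements = [a.element for a in atoms]
    coords = structure.coords
    pairs = _bond_pairs(elements, coords)

    neighbors: list[list[int]] = [[] for _ in atoms]
    for i, j in pairs:
        neighbors[i].append(j)
        neighbors[j].append(i)

    heavy_idx = [i for i, e in enumerate(elements) if e != "H"]
    heavy_set = set(heavy_idx)
    heavy_pairs = [(i, j) for i, j in pairs if i in heavy_set and j in heavy_set]

    in_ring = np.zeros(len(atoms), dtype=bool)
    aromatic = np.zeros(len(atoms), dtype=bool)
    for cycle in _ring_memberships(len(atoms), heavy_pairs):
        in_ring[cycle] = True
        if len(cycle) in (5, 6) and all(elements[i] in ("C", "N", "O", "S") for i in cycle):
            if _is_planar(coords[cycle]):
                aromatic[cycle] = True

    out = []
    for i in heavy_idx:
        elem = elements[i]
        vec = np.zeros(N_CHANNELS, dtype=np.float32)
        cls = _element_class(elem)
        if cls is not None:
            vec[cls] = 1.0
        elif elem != "Du":
            logger.debug("atom %d (%s): outside all element classes", atoms[i].serial, elem)

        nbrs = neighbors[i]
        heavy_nbrs = [j for j in nbrs if elements[j] != "H"]
        hetero_nbrs = [j for j in heavy_nbrs if elements[j] not in ("C", "H")]
        h_nbrs = [j for j in nbrs if elements[j] == "H"]

        vec[9] = _hybridization(elem, coords, i, nbrs, bool(aromatic[i]))
        vec[10] = len(heavy_nbrs)
        vec[11] = len(hetero_nbrs)
        vec[12] = 1.0 if elem == "C" and not hetero_nbrs else 0.0
        vec[13] = 1.0 if aromatic[i] else 0.0
        vec[14] = 1.0 if elem in ("N", "O") else 0.0
        vec[15] = 1.0 if elem in ("N", "O", "S") and h_nbrs else 0.0
        vec[16] = 1.0 if in_ring[i] else 0.0
        vec[17] = atoms[i].partial_charge
        out.append((coords[i].copy(), vec))
    return out


def _hybridization(
    elem: str, coords: np.ndarray, i: int, nbrs: list[int], aromatic: bool
) -> float:
    """Geometric hybridization heuristic: sp=1, sp2=2, sp3=3."""
    if elem in METALS or elem == "Du":
        return 0.0
    if aromatic:
        return 2.0
    n = len(nbrs)
    if n >= 4:
        return 3.0
    if n == 3:
        return 2.0 if _is_planar(coords[[i] + nbrs], tol=0.1) else 3.0
    if n == 2:
        v1 = coords[nbrs[0]] - coords[i]
        v2 = coords[nbrs[1]] - coords[i]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
        return 1.0 if cosang < -0.95 else 3.0
    return 3.0
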