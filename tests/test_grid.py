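"""Lattice geometry, voxelization and on-lattice augmentation."""

import numpy as np
import pytest

from pocketseg import (
    AtomRecord,
    GridSpec,
    InputGrid,
    MolecularStructure,
    PocketMask,
    augment,
    make_grid,
    make_pocket_mask,
    protein_center,
)
from pocketseg.grid import ROTATIONS, rotation_matrix


def atom(i, element, xyz, charge=0.0):
    return AtomRecord(i, f"{element}{i}", element, "RES", i, "A", xyz, charge)


class TestGridSpec:
    def test_default_lattice_spans_70_angstrom(self):
        spec = GridSpec()
        assert spec.points_per_axis == 36
        assert spec.spacing == 2.0
        assert spec.span == pytest.approx(70.0)

    def test_node_coordinates_follow_origin_plus_spacing(self):
        spec = GridSpec(center=(1.0, 2.0, 3.0), spacing=2.0, points_per_axis=4)
        np.testing.assert_allclose(spec.origin, [1.0 - 3.0, 2.0 - 3.0, 3.0 - 3.0])
        np.testing.assert_allclose(spec.node_coords(np.array([[3, 3, 3]]))[0], [4.0, 5.0, 6.0])

    @pytest.mark.parametrize("bad", [dict(spacing=0.0), dict(points_per_axis=1)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            GridSpec(**bad)


class TestProteinCenter:
    def test_single_atom(self):
        s = MolecularStructure([atom(1, "C", (1.0, 2.0, 3.0))])
        np.testing.assert_allclose(protein_center(s), [1, 2, 3])

    def test_symmetric_pair(self):
        s = MolecularStructure([atom(1, "C", (5.0, 0, 0)), atom(2, "C", (-5.0, 0, 0))])
        np.testing.assert_allclose(protein_center(s), [0, 0, 0])

    def test_hydrogens_do_not_contribute(self):
        s = MolecularStructure([atom(1, "C", (1, 1, 1)), atom(2, "H", (99, 99, 99))])
        np.testing.assert_allclose(protein_center(s), [1, 1, 1])

    def test_matches_mean_oracle_on_toy_fixture(self, toy_protein):
        heavy = [a.coords for a in toy_protein.atoms if a.element != "H"]
        np.testing.assert_allclose(protein_center(toy_protein), np.mean(heavy, axis=0), atol=1e-9)


class TestMakeGrid:
    def test_empty_atom_list_gives_zero_grid(self):
        g = make_grid([], GridSpec())
        assert g.values.shape == (36, 36, 36, 18)
        assert not g.values.any()

    def test_atom_at_center_lands_on_node_18(self):
        spec = GridSpec(center=(0.0, 0.0, 0.0))
        # brute-force nearest-node search over all nodes, half-up on ties
        coords = np.array([0.0, 0.0, 0.0])
        axis_nodes = spec.origin[0] + spec.spacing * np.arange(36)
        dists = np.abs(axis_nodes - 0.0)
        candidates = np.flatnonzero(dists == dists.min())
        assert candidates.tolist() == [17, 18]  # exact tie on the even lattice
        vec = np.zeros(18, dtype=np.float32)
        vec[1] = 1.0
        g = make_grid([(coords, vec)], spec)
        nz = np.argwhere(g.values.any(axis=-1))
        np.testing.assert_array_equal(nz, [[18, 18, 18]])  # half-up tie-break

    def test_feature_sum_is_conserved_for_retained_atoms(self):
        rng = np.random.default_rng(0)
        spec = GridSpec()
        feats = [(rng.uniform(-30, 30, 3), rng.random(18).astype(np.float32)) for _ in range(200)]
        g = make_grid(feats, spec)
        total = np.sum([f for _, f in feats], axis=0)
        np.testing.assert_allclose(g.values.sum(axis=(0, 1, 2)), total, rtol=1e-5)

    def test_atoms_outside_lattice_are_dropped(self):
        spec = GridSpec()
        vec = np.ones(18, dtype=np.float32)
        g = make_grid([(np.array([500.0, 0.0, 0.0]), vec)], spec)
        assert not g.values.any()


class TestMakePocketMask:
    def test_no_points_yields_empty_flagged_mask(self):
        mask = make_pocket_mask(MolecularStructure([]), GridSpec())
        assert mask.empty
        assert not mask.values.any()

    def test_point_on_node_sets_exactly_one_voxel(self):
        spec = GridSpec(center=(0.0, 0.0, 0.0))
        node = spec.node_coords(np.array([[10, 11, 12]]))[0]
        cloud = MolecularStructure([atom(1, "Du", tuple(node))])
        mask = make_pocket_mask(cloud, spec)
        assert mask.values.sum() == 1
        assert mask.values[10, 11, 12] == 1
        assert not mask.empty

    def test_matches_brute_force_cell_assignment(self):
        rng = np.random.default_rng(11)
        spec = GridSpec(center=(0.0, 0.0, 0.0), spacing=2.0, points_per_axis=10)
        pts = rng.uniform(-9, 9, size=(1000, 3))
        cloud = MolecularStructure([atom(i + 1, "Du", tuple(p)) for i, p in enumerate(pts)])
        mask = make_pocket_mask(cloud, spec)
        oracle = np.zeros((10, 10, 10), dtype=np.uint8)
        for p in pts:
            idx = []
            for ax in range(3):
                nodes = spec.origin[ax] + spec.spacing * np.arange(10)
                d = np.abs(nodes - p[ax])
                ties = np.flatnonzero(d == d.min())
                idx.append(ties.max())  # half-up = larger index on exact tie
            oracle[tuple(idx)] = 1
        np.testing.assert_array_equal(mask.values, oracle)


class TestAugment:
    @staticmethod
    def pair(seed=0, points=12):
        rng = np.random.default_rng(seed)
        spec = GridSpec(points_per_axis=points)
        grid = InputGrid(spec, rng.random((points, points, points, 18)).astype(np.float32))
        mask = PocketMask(spec, (rng.random((points, points, points)) < 0.1).astype(np.uint8))
        return grid, mask

    def test_identity_rotation_and_zero_shift(self):
        grid, mask = self.pair()
        g2, m2 = augment(grid, mask, 0, (0, 0, 0))
        np.testing.assert_array_equal(g2.values, grid.values)
        np.testing.assert_array_equal(m2.values, mask.values)

    def test_all_rotation_matrices_are_proper_and_distinct(self):
        mats = [rotation_matrix(i) for i in range(24)]
        assert len(ROTATIONS) == 24
        for m in mats:
            assert round(np.linalg.det(m)) == 1
        assert len({m.tobytes() for m in mats}) == 24

    @pytest.mark.parametrize("rotation_id", range(24))
    def test_rotation_preserves_pocket_voxel_count(self, rotation_id):
        grid, mask = self.pair(seed=rotation_id)
        _, m2 = augment(grid, mask, rotation_id, (0, 0, 0))
        assert m2.values.sum() == mask.values.sum()

    def test_every_rotation_has_finite_order_dividing_group(self):
        # applying any proper cube rotation repeatedly returns to identity
        # within 4 steps (element orders are 1, 2, 3 or 4)
        grid, mask = self.pair(seed=5)
        for rid in range(24):
            g = grid
            m = mask
            for reps in range(1, 5):
                g, m = augment(g, m, rid, (0, 0, 0))
                if np.array_equal(g.values, grid.values):
                    break
            order = reps
            assert np.array_equal(g.values, grid.values) or order <= 4
        # and the 90-degree rotation about one axis has order exactly 4
        mat_orders = []
        for rid in range(24):
            m = rotation_matrix(rid)
            acc = np.eye(3, dtype=int)
            for reps in range(1, 5):
                acc = m @ acc
                if np.array_equal(acc, np.eye(3, dtype=int)):
                    break
            mat_orders.append(reps)
        assert set(mat_orders) <= {1, 2, 3, 4}
        assert mat_orders.count(1) == 1  # identity only

    def test_array_rotation_agrees_with_matrix_action(self):
        # voxel-by-voxel oracle: rotating indices about the center with the
        # signed-permutation matrix reproduces the array transform
        grid, mask = self.pair(seed=3, points=6)
        c = (6 - 1) / 2.0
        for rid in [1, 5, 11, 17, 23]:
            _, m2 = augment(grid, mask, rid, (0, 0, 0))
            mat = rotation_matrix(rid)
            oracle = np.zeros_like(mask.values)
            for idx in np.argwhere(mask.values):
                new = mat @ (idx - c) + c
                oracle[tuple(np.round(new).astype(int))] = 1
            np.testing.assert_array_equal(m2.values, oracle)

    def test_translation_shifts_and_zero_fills(self):
        grid, mask = self.pair(seed=2)
        g2, m2 = augment(grid, mask, 0, (1, 0, 0))
        np.testing.assert_array_equal(g2.values[1:], grid.values[:-1])
        assert not g2.values[0].any()

    def test_coregistration_of_grid_and_mask(self):
        spec = GridSpec(points_per_axis=12)
        g = np.zeros((12, 12, 12, 18), dtype=np.float32)
        m = np.zeros((12, 12, 12), dtype=np.uint8)
        g[3, 4, 5, 1] = 1.0
        m[3, 4, 5] = 1
        for rid in range(24):
            g2, m2 = augment(InputGrid(spec, g), PocketMask(spec, m), rid, (1, -2, 0))
            marked = np.argwhere(m2.values)
            lit = np.argwhere(g2.values[..., 1] > 0)
            np.testing.assert_array_equal(marked, lit)

    def test_invalid_rotation_and_translation_rejected(self):
        grid, mask = self.pair()
        with pytest.raises(ValueError):
            augment(grid, mask, 24, (0, 0, 0))
        with pytest.raises(ValueError):
            augment(grid, mask, 0, (4, 0, 0))
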