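"""Voxel grids: closed-form weights, oracles, translation/rotation behavior."""

import numpy as np
import pytest

from plbap import (
    Atom,
    GridSpec,
    MolecularComplex,
    Molecule,
    ValidationError,
    augment_rotations,
    fill_aggregate,
    fill_contribution,
    ligand_center,
)
from plbap.grid_featurizer import cube_rotations

from conftest import random_rigid_motion

SMALL = GridSpec(extent=8.0, resolution=1.0)


def _complex_of(protein_atoms, ligand_atoms) -> MolecularComplex:
    return MolecularComplex(
        "fix",
        Molecule(atoms=protein_atoms, role="protein"),
        Molecule(atoms=ligand_atoms, role="ligand"),
    )


def _single_atom_complex(offset, vdw=1.7, role="ligand"):
    """One ligand atom at the origin defining the center, plus one probe atom."""
    anchor = Atom(index=0, element="C", coords=np.zeros(3), vdw_radius=vdw)
    if role == "ligand":
        probe = Atom(index=1, element="C", coords=np.asarray(offset, float),
                     vdw_radius=vdw)
        return _complex_of([], [anchor, probe])
    probe = Atom(index=0, element="C", coords=np.asarray(offset, float),
                 vdw_radius=vdw)
    return _complex_of([probe], [anchor])


def _rotate_grid_indices(values: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Index-space image of a grid under a signed permutation rotation.

    The grid filled from rotated coordinates satisfies
    ``grid_R[v] = grid_I[R^T v]``; for a cube-group rotation ``R^T v`` is an
    exact index map on the symmetric lattice.
    """
    g = values.shape[0]
    rt = rotation.T
    idx = np.indices((g, g, g))
    src = np.empty_like(idx)
    for row in range(3):
        col = int(np.flatnonzero(rt[row])[0])
        sign = rt[row, col]
        src[row] = idx[col] if sign > 0 else (g - 1) - idx[col]
    # note: source index of output position i is built from output indices
    out = np.empty_like(values)
    out[...] = values[src[0], src[1], src[2], :]
    return out


class TestLigandCenter:
    def test_mean_of_ligand_coords(self):
        complex_ = _complex_of([], [
            Atom(index=0, element="C", coords=np.zeros(3)),
            Atom(index=1, element="C", coords=np.array([2.0, 0, 0])),
        ])
        assert np.allclose(ligand_center(complex_), [1.0, 0, 0])

    def test_translation_moves_center(self, small_complex):
        t = np.array([3.0, -2.0, 7.0])
        moved = small_complex.transformed(translation=t)
        assert np.allclose(ligand_center(moved), ligand_center(small_complex) + t,
                           atol=1e-9)


class TestContributionFilling:
    def test_weight_at_vdw_distance(self):
        # probe ligand atom exactly r_vdw away from a lattice point
        complex_ = _single_atom_complex((0.0, 0.0, 0.0), vdw=1.0)
        # place the pair symmetric about origin so the center is origin
        complex_.ligand.atoms[0].coords = np.array([-1.0, 0.0, 0.0])
        complex_.ligand.atoms[1].coords = np.array([1.0, 0.0, 0.0])
        spec = GridSpec(extent=4.0, resolution=1.0, layout="single",
                        channels=("excluded_volume",))
        grid = fill_contribution(complex_, spec)
        g = spec.points_per_side  # 5, center voxel index 2
        # each atom is 1.0 A (= r_vdw) from the lattice point at the origin
        center_value = grid.values[2, 2, 2, 0]
        assert center_value == pytest.approx(2 * (1 - np.exp(-1.0)), abs=1e-12)

    def test_weight_limit_at_zero_distance(self):
        complex_ = _single_atom_complex((0.0, 0.0, 0.0))
        complex_.ligand.atoms[1].coords = np.zeros(3)  # both atoms at origin
        spec = GridSpec(extent=4.0, resolution=1.0, layout="single",
                        channels=("excluded_volume",))
        grid = fill_contribution(complex_, spec)
        assert grid.values[2, 2, 2, 0] == pytest.approx(2.0)  # weight 1 per atom

    def test_far_atom_contributes_negligibly(self):
        vdw = 1.0
        d = 4.0 * vdw
        expected = 1 - np.exp(-(1.0 / 4.0) ** 12)
        assert expected == pytest.approx(5.96e-8, rel=1e-2)
        complex_ = _complex_of(
            [Atom(index=0, element="C", coords=np.array([d, 0, 0]), vdw_radius=vdw)],
            [Atom(index=0, element="C", coords=np.zeros(3), vdw_radius=vdw)])
        spec = GridSpec(extent=2.0, resolution=1.0, layout="two_grid",
                        channels=("excluded_volume",))
        grid = fill_contribution(complex_, spec)
        # protein channel value at the origin voxel equals the tiny weight
        assert grid.values[1, 1, 1, 0] == pytest.approx(expected, abs=1e-14)


class TestAggregateFilling:
    def test_atom_on_lattice_point(self):
        complex_ = _single_atom_complex((0, 0, 0))
        complex_.ligand.atoms[0].coords = np.array([-1.0, 0, 0])
        complex_.ligand.atoms[1].coords = np.array([1.0, 0, 0])
        spec = GridSpec(extent=4.0, resolution=1.0, layout="single",
                        channels=("excluded_volume",))
        grid = fill_aggregate(complex_, spec)
        assert grid.values[1, 2, 2, 0] == 1.0  # atom at x=-1
        assert grid.values[3, 2, 2, 0] == 1.0  # atom at x=+1
        assert grid.values.sum() == 2.0

    def test_two_atoms_in_one_cell_sum(self):
        atoms = [Atom(index=i, element="C", coords=np.array([0.1 * i, 0, 0]))
                 for i in range(2)]
        # symmetric pair keeps the center at 0.05; both round to the origin cell
        complex_ = _complex_of([], atoms)
        spec = GridSpec(extent=4.0, resolution=1.0, layout="single",
                        channels=("excluded_volume",))
        grid = fill_aggregate(complex_, spec)
        assert grid.values.max() == 2.0
        assert grid.values.sum() == 2.0

    def test_atoms_outside_extent_ignored(self):
        complex_ = _complex_of(
            [Atom(index=0, element="C", coords=np.array([30.0, 0, 0]))],
            [Atom(index=0, element="C", coords=np.zeros(3))])
        spec = GridSpec(extent=4.0, resolution=1.0)
        grid = fill_aggregate(complex_, spec)
        protein_block = grid.values[..., :len(spec.channels)]
        assert protein_block.sum() == 0

    def test_matches_nearest_lattice_oracle(self, rng, small_complex):
        spec = GridSpec(extent=12.0, resolution=1.5, layout="two_grid",
                        channels=("excluded_volume", "hbond_acceptor"))
        grid = fill_aggregate(small_complex, spec)
        # oracle: nearest lattice point by full argmin (first occurrence on ties)
        center = ligand_center(small_complex)
        axis = spec.axis_coords()
        g = spec.points_per_side
        lattice = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"),
                           axis=-1).reshape(-1, 3)
        expected = np.zeros_like(grid.values)
        for offset, mol in ((0, small_complex.protein),
                            (len(spec.channels), small_complex.ligand)):
            for atom in mol.atoms:
                rel = atom.coords - center
                if np.any(np.abs(rel) > spec.extent / 2):
                    continue
                flat = int(np.argmin(np.linalg.norm(lattice - rel, axis=1)))
                i, j, k = np.unravel_index(flat, (g, g, g))
                expected[i, j, k, offset] += 1.0
                expected[i, j, k, offset + 1] += float(
                    atom.flags["hbond_acceptor"])
        assert np.array_equal(grid.values, expected)


class TestLayoutBookkeeping:
    def test_default_two_grid_channel_count(self):
        spec = GridSpec(extent=20.0, resolution=1.0)
        assert spec.points_per_side == 21
        assert spec.n_channels == 16

    def test_cells_mode_reproduces_cell_count_convention(self):
        assert GridSpec(extent=24.0, resolution=1.0, cells_mode=True).points_per_side == 24
        assert GridSpec(extent=23.0, resolution=1.0).points_per_side == 24


class TestSymmetry:
    @pytest.mark.parametrize("fill", [fill_contribution, fill_aggregate])
    def test_translation_invariance(self, rng, small_complex, fill):
        base = fill(small_complex, SMALL)
        for _ in range(5):
            t = rng.uniform(-30, 30, size=3)
            moved = fill(small_complex.transformed(translation=t), SMALL)
            if fill is fill_aggregate:
                assert np.array_equal(moved.values, base.values)
            else:
                assert np.allclose(moved.values, base.values, atol=1e-9)

    @pytest.mark.parametrize("fill", [fill_contribution, fill_aggregate])
    def test_right_angle_rotation_equivariance(self, small_complex, fill):
        base = fill(small_complex, SMALL)
        for rot in cube_rotations(24):
            rotated = fill(small_complex, SMALL, rotation=rot)
            expected = _rotate_grid_indices(base.values, rot)
            if fill is fill_aggregate:
                assert np.array_equal(rotated.values, expected)
            else:
                assert np.allclose(rotated.values, expected, atol=1e-12)

    def test_permutation_invariance(self, rng, small_complex):
        perm = rng.permutation(len(small_complex.protein))
        shuffled = Molecule(
            atoms=[Atom(index=i,
                        element=small_complex.protein.atoms[p].element,
                        coords=small_complex.protein.atoms[p].coords,
                        vdw_radius=small_complex.protein.atoms[p].vdw_radius,
                        flags=dict(small_complex.protein.atoms[p].flags))
                   for i, p in enumerate(perm)],
            role="protein")
        permuted = MolecularComplex("perm", shuffled, small_complex.ligand)
        for fill in (fill_contribution, fill_aggregate):
            assert np.allclose(fill(permuted, SMALL).values,
                               fill(small_complex, SMALL).values, atol=1e-12)


class TestAugmentation:
    def test_identity_rotation_first(self, small_complex):
        grids = augment_rotations(small_complex, SMALL, 4, strategy="aggregate")
        assert len(grids) == 4
        assert np.array_equal(grids[0].values,
                              fill_aggregate(small_complex, SMALL).values)

    def test_24_rotations_unique_matrices(self):
        mats = cube_rotations(24)
        assert len(mats) == 24
        assert len({tuple(m.ravel()) for m in mats}) == 24
        assert all(round(np.linalg.det(m)) == 1 for m in mats)

    def test_z_symmetric_fixture_gives_identical_grids(self):
        # 4 ligand atoms forming a z-axis 4-fold symmetric cross
        atoms = [Atom(index=i, element="C", coords=np.asarray(c, float))
                 for i, c in enumerate([(2, 0, 0), (-2, 0, 0), (0, 2, 0), (0, -2, 0)])]
        complex_ = _complex_of([], atoms)
        spec = GridSpec(extent=6.0, resolution=1.0, layout="single",
                        channels=("excluded_volume",))
        grids = augment_rotations(complex_, spec, 4, strategy="aggregate")
        for grid in grids[1:]:
            assert np.array_equal(grid.values, grids[0].values)

    def test_unsupported_rotation_count_rejected(self, small_complex):
        with pytest.raises(ValidationError):
            augment_rotations(small_complex, SMALL, 7)
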