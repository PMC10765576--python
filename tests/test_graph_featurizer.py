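"""Binding-site graphs: node canonicalization and the four adjacency variants."""

import numpy as np
import pytest

from plbap import (
    Atom,
    GaussianAdjacencyParams,
    MolecularComplex,
    Molecule,
    ValidationError,
    adjacency_covalent_noncovalent,
    adjacency_distance_valued,
    adjacency_gaussian,
    adjacency_shells,
    build_nodes,
)
from plbap.graph_featurizer import PAFNUCY_NODE_FEATURES, ComplexGraph

from conftest import random_rigid_motion


def _graph_from_coords(coords, bonds=frozenset(), n_max=None) -> ComplexGraph:
    coords = np.asarray(coords, float)
    n = len(coords)
    n_max = n_max or n
    mask = np.zeros(n_max, bool)
    mask[:n] = True
    return ComplexGraph(node_features=np.zeros((n_max, 1)), node_mask=mask,
                        coords=coords, bonds=set(bonds), n_real=n)


def _pair_graph(distance, bonded=False) -> ComplexGraph:
    bonds = {(0, 1)} if bonded else set()
    return _graph_from_coords([[0, 0, 0], [distance, 0, 0]], bonds)


class TestBuildNodes:
    def test_mask_and_padding(self):
        ligand = Molecule(atoms=[Atom(index=i, element="C",
                                      coords=np.array([float(i), 0, 0]))
                                 for i in range(5)], role="ligand")
        complex_ = MolecularComplex("x", Molecule(atoms=[], role="protein"), ligand)
        graph = build_nodes(complex_, cutoff=6.0, n_max=8)
        assert graph.node_mask.tolist() == [True] * 5 + [False] * 3
        assert np.all(graph.node_features[5:] == 0)
        assert graph.node_features.shape == (8, len(PAFNUCY_NODE_FEATURES))

    def test_reference_envelope(self, medium_complex):
        graph = build_nodes(medium_complex, cutoff=6.0, n_max=400)
        assert graph.n_real < 400
        assert graph.node_features.shape == (400, 18)

    def test_ligand_atoms_precede_protein(self, medium_complex):
        graph = build_nodes(medium_complex, cutoff=6.0, n_max=400)
        sign_col = PAFNUCY_NODE_FEATURES.index("molecule_sign")
        signs = graph.node_features[:graph.n_real, sign_col]
        n_lig = len(medium_complex.ligand)
        assert np.all(signs[:n_lig] == 1.0)
        assert np.all(signs[n_lig:] == -1.0)

    def test_truncation_keeps_nearest_protein_atoms(self, medium_complex):
        full = build_nodes(medium_complex, cutoff=12.0, n_max=400)
        n_lig = len(medium_complex.ligand)
        trimmed = build_nodes(medium_complex, cutoff=12.0, n_max=n_lig + 10)
        assert trimmed.n_real == n_lig + 10
        assert np.allclose(trimmed.coords, full.coords[:n_lig + 10])

    def test_oversized_ligand_rejected(self, medium_complex):
        with pytest.raises(ValidationError):
            build_nodes(medium_complex, cutoff=6.0,
                        n_max=len(medium_complex.ligand) - 1)

    def test_permuted_input_gives_same_graph(self, medium_complex, rng):
        base = build_nodes(medium_complex, cutoff=6.0, n_max=200)

        def shuffle(mol, role):
            perm = rng.permutation(len(mol))
            return Molecule(
                atoms=[Atom(index=i, element=mol.atoms[p].element,
                            coords=mol.atoms[p].coords,
                            vdw_radius=mol.atoms[p].vdw_radius,
                            partial_charge=mol.atoms[p].partial_charge,
                            heavy_neighbor_count=mol.atoms[p].heavy_neighbor_count,
                            hetero_neighbor_count=mol.atoms[p].hetero_neighbor_count,
                            flags=dict(mol.atoms[p].flags))
                       for i, p in enumerate(perm)],
                bonds=[(int(np.argwhere(perm == i)[0, 0]),
                        int(np.argwhere(perm == j)[0, 0]), order)
                       for i, j, order in mol.bonds],
                role=role)

        permuted = MolecularComplex(
            "perm", shuffle(medium_complex.protein, "protein"),
            shuffle(medium_complex.ligand, "ligand"))
        other = build_nodes(permuted, cutoff=6.0, n_max=200)
        assert np.allclose(other.node_features, base.node_features, atol=1e-12)
        assert np.allclose(other.coords, base.coords, atol=1e-12)
        assert other.bonds == base.bonds


class TestShellAdjacency:
    def test_hand_binning(self):
        adjacency = adjacency_shells(_pair_graph(3.0), 3)
        # shells (0, 4/3], (4/3, 8/3], (8/3, 4]: 3.0 lands in the third
        assert adjacency[0, 1, 2] == 1
        assert adjacency[1, 0, 2] == 1
        assert adjacency.sum() == 2

    def test_beyond_four_angstrom_empty(self):
        assert adjacency_shells(_pair_graph(4.2), 3).sum() == 0

    def test_each_pair_in_at_most_one_slice(self, rng):
        graph = _graph_from_coords(rng.uniform(-4, 4, size=(20, 3)))
        adjacency = adjacency_shells(graph, 4)
        assert (adjacency.sum(axis=2) <= 1).all()


class TestCovalentNoncovalent:
    def test_bonded_pair_excluded_from_distance_slices(self):
        adjacency = adjacency_covalent_noncovalent(_pair_graph(1.5, bonded=True),
                                                   thresholds=(3.0,))
        assert adjacency[0, 1, 0] == 1
        assert adjacency[0, 1, 1] == 0

    @pytest.mark.parametrize("distance,expected", [(2.9, 1.0), (3.1, 0.0)])
    def test_distance_threshold_strict(self, distance, expected):
        adjacency = adjacency_covalent_noncovalent(_pair_graph(distance),
                                                   thresholds=(3.0,))
        assert adjacency[0, 1, 0] == 0
        assert adjacency[0, 1, 1] == expected


class TestDistanceValued:
    @pytest.mark.parametrize("distance,slice_idx,value", [
        (1.2, 0, 1.2),
        (1.5, 0, 1.5),   # boundary goes to the lower shell
        (3.0, 1, 3.0),
        (5.0, None, 0.0),
    ])
    def test_values_and_shells(self, distance, slice_idx, value):
        adjacency = adjacency_distance_valued(_pair_graph(distance))
        if slice_idx is None:
            assert adjacency.sum() == 0
        else:
            assert adjacency[0, 1, slice_idx] == pytest.approx(value)
            other = 1 - slice_idx
            assert adjacency[0, 1, other] == 0


class TestGaussianAdjacency:
    def test_covalent_pair_is_one(self):
        slice_ = adjacency_gaussian(_pair_graph(1.4, bonded=True),
                                    GaussianAdjacencyParams())
        assert slice_[0, 1] == 1.0

    def test_noncovalent_gaussian_weight(self):
        params = GaussianAdjacencyParams(mu=0.0, sigma=1.0, cutoff=5.0)
        slice_ = adjacency_gaussian(_pair_graph(2.0), params)
        assert slice_[0, 1] == pytest.approx(np.exp(-4.0), abs=1e-12)
        assert slice_[0, 1] < 1.0

    def test_at_mu_reaches_one(self):
        params = GaussianAdjacencyParams(mu=3.0, sigma=2.0)
        slice_ = adjacency_gaussian(_pair_graph(3.0), params)
        assert slice_[0, 1] == 1.0

    def test_beyond_cutoff_zero(self):
        params = GaussianAdjacencyParams(cutoff=5.0)
        assert adjacency_gaussian(_pair_graph(5.5), params)[0, 1] == 0.0

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValidationError):
            GaussianAdjacencyParams(sigma=0.0)


class TestAdjacencyInvariants:
    def _all_variants(self, graph):
        yield adjacency_shells(graph, 3)
        yield adjacency_covalent_noncovalent(graph, thresholds=(3.0,))
        yield adjacency_distance_valued(graph)
        yield adjacency_gaussian(graph, GaussianAdjacencyParams())[..., None]

    def test_symmetric_zero_diagonal_zero_padding(self, rng):
        coords = rng.uniform(-4, 4, size=(15, 3))
        bonds = {(0, 1), (3, 7)}
        graph = _graph_from_coords(coords, bonds, n_max=20)
        for adjacency in self._all_variants(graph):
            for k in range(adjacency.shape[2]):
                s = adjacency[:, :, k]
                assert np.array_equal(s, s.T)
                assert np.all(np.diag(s) == 0)
                assert np.all(s[15:, :] == 0) and np.all(s[:, 15:] == 0)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(-4, 4, size=(12, 3))
        graph = _graph_from_coords(coords, {(0, 1)})
        base = [a.copy() for a in self._all_variants(graph)]
        for _ in range(5):
            rot, tr = random_rigid_motion(rng)
            moved = _graph_from_coords(coords @ rot.T + tr, {(0, 1)})
            for a, b in zip(self._all_variants(moved), base):
                # binary/binned variants are bit-stable, valued ones to 1e-9
                assert np.allclose(a, b, atol=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(-3, 3, size=(30, 3))
        bonds = {(0, 1), (2, 3), (10, 20)}
        graph = _graph_from_coords(coords, bonds)
        n = len(coords)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d[i, j] = np.linalg.norm(coords[i] - coords[j])

        shells = adjacency_shells(graph, 3)
        for i in range(n):
            for j in range(n):
                for k in range(3):
                    lo, hi = 4 * k / 3, 4 * (k + 1) / 3
                    expected = float(i != j and lo < d[i, j] <= hi)
                    assert shells[i, j, k] == expected

        gauss = adjacency_gaussian(graph, GaussianAdjacencyParams(mu=1.0, sigma=2.0))
        for i in range(n):
            for j in range(n):
                if i == j:
                    expected = 0.0
                elif (min(i, j), max(i, j)) in bonds:
                    expected = 1.0
                elif d[i, j] <= 5.0:
                    expected = np.exp(-((d[i, j] - 1.0) ** 2) / 2.0)
                else:
                    expected = 0.0
                assert gauss[i, j] == pytest.approx(expected, abs=1e-12)
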