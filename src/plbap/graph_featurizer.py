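"""Binding-site graphs: padded node-feature matrices and adjacency tensors.

The node set is every ligand atom plus the protein atoms within a crop
cutoff of any ligand atom, padded to a fixed size ``N_max`` for batching.
Nodes are canonically ordered -- ligand atoms first (original order), then
protein atoms by ascending minimum distance to the ligand, ties by index --
so that two atom orderings of the same complex produce the same graph.

Four adjacency constructions are provided, all symmetric per slice, with a
zero diagonal (self-loops are added by the propagation rule, not stored):

* ``shells`` -- N_et binary slices over the shells ((4(k-1)/N_et, 4k/N_et];
* ``cov_noncov`` -- slice 0 covalent bonds, later slices distance < t_k
  excluding covalently bonded pairs;
* ``distance`` -- distances as values over the two shells (0,1.5], (1.5,4.5];
* ``gaussian`` -- 1 for covalent pairs, exp(-(d - mu)^2 / sigma) for
  noncovalent pairs within a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complex_model import (
    MolecularComplex,
    ValidationError,
    pairwise_distances,
)
from .grid_featurizer import atom_property

__all__ = [
    "PAFNUCY_NODE_FEATURES",
    "ComplexGraph",
    "GaussianAdjacencyParams",
    "build_nodes",
    "adjacency_shells",
    "adjacency_covalent_noncovalent",
    "adjacency_distance_valued",
    "adjacency_gaussian",
]

#: Default 18-column node-feature list: 9 one-hot element channels,
#: physico-chemical scalars, pharmacophore flags and a protein/ligand sign.
PAFNUCY_NODE_FEATURES = (
    "element_C", "element_N", "element_O", "element_S", "element_P",
    "element_F", "element_Cl", "element_Br", "element_other",
    "partial_charge", "heavy_neighbor_count", "hetero_neighbor_count",
    "hydrophobic", "aromatic", "hbond_donor", "hbond_acceptor",
    "ring_member", "molecule_sign",
)


def _node_feature(atom, name: str, is_ligand: bool) -> float:
    if name.startswith("element_"):
        el = name.split("_", 1)[1]
        if el == "other":
            known = {f.split("_", 1)[1] for f in PAFNUCY_NODE_FEATURES
                     if f.startswith("element_")} - {"other"}
            return float(atom.element not in known)
        return float(atom.element == el)
    if name == "molecule_sign":
        return 1.0 if is_ligand else -1.0
    return atom_property(atom, name)


@dataclass
class ComplexGraph:
    """Padded binding-site graph.

    ``node_features``: N_max x M_f (rows past N_real are zero);
    ``node_mask``: length-N_max booleans; ``coords``: N_real x 3 used by the
    distance-based adjacency builders; ``bonds``: covalent pairs in node
    indices; ``edge_features``: optional one-hot bond-type table.
    """

    node_features: np.ndarray
    node_mask: np.ndarray
    coords: np.ndarray
    bonds: set[tuple[int, int]]
    n_real: int
    edge_features: np.ndarray | None = None

    @property
    def n_max(self) -> int:
        return self.node_features.shape[0]


@dataclass(frozen=True)
class GaussianAdjacencyParams:
    """Parameters of the Gaussian noncovalent adjacency.

    mu (A) and sigma (A^2, the exponent scale) have no canonical published
    values; they are mandatory configuration with defaults mu=0, sigma=1.
    """

    mu: float = 0.0
    sigma: float = 1.0
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")


_BOND_ONEHOT = {"single": 0, "double": 1, "triple": 2, "aromatic": 3}


def build_nodes(complex_: MolecularComplex, cutoff: float, n_max: int,
                feature_list: tuple[str, ...] = PAFNUCY_NODE_FEATURES,
                ) -> ComplexGraph:
    """Crop, canonically order and pad the binding-site node set.

    If more than ``n_max`` atoms survive the crop, the farthest protein
    atoms are dropped deterministically; a ligand alone exceeding ``n_max``
    is an error.
    """
    ligand, protein = complex_.ligand, complex_.protein
    n_lig = len(ligand)
    if n_lig > n_max:
        raise ValidationError(
            f"{complex_.identifier}: ligand ({n_lig} atoms) exceeds n_max={n_max}")

    # canonical ligand order: ascending distance from the ligand centroid
    # (ties by original index), so reindexed inputs map to the same graph
    centroid = ligand.coords.mean(axis=0)
    d_centroid = np.linalg.norm(ligand.coords - centroid, axis=1)
    lig_order = np.lexsort((np.arange(n_lig), d_centroid))

    if len(protein):
        d_min = pairwise_distances(protein.coords, ligand.coords).min(axis=1)
        kept = np.flatnonzero(d_min <= cutoff)
        # ascending min-distance to ligand, ties by original index
        kept = kept[np.lexsort((kept, d_min[kept]))]
        kept = kept[: n_max - n_lig]
    else:
        kept = np.zeros(0, dtype=int)

    ordered = ([ligand.atoms[int(i)] for i in lig_order]
               + [protein.atoms[int(i)] for i in kept])
    n_real = len(ordered)
    is_ligand = [True] * n_lig + [False] * len(kept)

    features = np.zeros((n_max, len(feature_list)))
    for row, (atom, lig) in enumerate(zip(ordered, is_ligand)):
        features[row] = [_node_feature(atom, name, lig) for name in feature_list]
    mask = np.zeros(n_max, dtype=bool)
    mask[:n_real] = True
    coords = np.stack([a.coords for a in ordered]) if n_real else np.zeros((0, 3))

    lig_map = {int(old): new for new, old in enumerate(lig_order)}
    prot_map = {int(old): n_lig + new for new, old in enumerate(kept)}
    bonds: set[tuple[int, int]] = set()
    bond_orders: dict[tuple[int, int], str] = {}
    for i, j, order in ligand.bonds:
        a, b = sorted((lig_map[i], lig_map[j]))
        bonds.add((a, b))
        bond_orders[(a, b)] = order
    for i, j, order in protein.bonds:
        if i in prot_map and j in prot_map:
            a, b = sorted((prot_map[i], prot_map[j]))
            bonds.add((a, b))
            bond_orders[(a, b)] = order

    edge_features = np.zeros((n_max, n_max, len(_BOND_ONEHOT)))
    for (a, b), order in bond_orders.items():
        edge_features[a, b, _BOND_ONEHOT[order]] = 1.0
        edge_features[b, a, _BOND_ONEHOT[order]] = 1.0

    return ComplexGraph(node_features=features, node_mask=mask, coords=coords,
                        bonds=bonds, n_real=n_real, edge_features=edge_features)


def _padded_distances(graph: ComplexGraph) -> np.ndarray:
    """N_max x N_max distances with inf on the diagonal and padded entries."""
    n, nm = graph.n_real, graph.n_max
    d = np.full((nm, nm), np.inf)
    if n:
        d[:n, :n] = pairwise_distances(graph.coords, graph.coords)
    np.fill_diagonal(d, np.inf)
    return d


def adjacency_shells(graph: ComplexGraph, n_edge_types: int) -> np.ndarray:
    """Binary N_max x N_max x N_et tensor over the equal-width shells
    ``(4(k-1)/N_et, 4k/N_et]`` spanning 0-4 A."""
    if n_edge_types < 1:
        raise ValidationError("n_edge_types must be >= 1")
    d = _padded_distances(graph)
    adjacency = np.zeros((graph.n_max, graph.n_max, n_edge_types))
    for k in range(n_edge_types):
        lo, hi = 4.0 * k / n_edge_types, 4.0 * (k + 1) / n_edge_types
        adjacency[:, :, k] = (d > lo) & (d <= hi)
    return adjacency


def _covalent_matrix(graph: ComplexGraph) -> np.ndarray:
    cov = np.zeros((graph.n_max, graph.n_max), dtype=bool)
    for i, j in graph.bonds:
        cov[i, j] = cov[j, i] = True
    return cov


def adjacency_covalent_noncovalent(graph: ComplexGraph,
                                   thresholds: tuple[float, ...] = (3.0,)
                                   ) -> np.ndarray:
    """Slice 0 = covalent bonds; slice k >= 1 = pairs at distance strictly
    below ``thresholds[k-1]`` that are not covalently bonded."""
    d = _padded_distances(graph)
    cov = _covalent_matrix(graph)
    adjacency = np.zeros((graph.n_max, graph.n_max, 1 + len(thresholds)))
    adjacency[:, :, 0] = cov
    for k, thr in enumerate(thresholds, start=1):
        adjacency[:, :, k] = (d < thr) & ~cov
    return adjacency


def adjacency_distance_valued(graph: ComplexGraph) -> np.ndarray:
    """Distance-valued tensor over the fixed shells (0, 1.5] and (1.5, 4.5]."""
    d = _padded_distances(graph)
    adjacency = np.zeros((graph.n_max, graph.n_max, 2))
    for k, (lo, hi) in enumerate(((0.0, 1.5), (1.5, 4.5))):
        in_shell = (d > lo) & (d <= hi)
        adjacency[:, :, k] = np.where(in_shell, d, 0.0)
    return adjacency


def adjacency_gaussian(graph: ComplexGraph,
                       params: GaussianAdjacencyParams) -> np.ndarray:
    """One N_max x N_max slice: 1 for covalent pairs, the Gaussian weight
    ``exp(-(d - mu)^2 / sigma)`` for noncovalent pairs with d <= cutoff.

    Note a noncovalent pair at exactly d = mu also reaches weight 1.
    """
    d = _padded_distances(graph)
    cov = _covalent_matrix(graph)
    with np.errstate(invalid="ignore", over="ignore"):
        gauss = np.exp(-((d - params.mu) ** 2) / params.sigma)
    slice_ = np.where(cov, 1.0, np.where(d <= params.cutoff, gauss, 0.0))
    np.fill_diagonal(slice_, 0.0)
    return slice_
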