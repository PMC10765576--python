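"""Intermolecular-contact (IMC) counting and contact profiling.

An intermolecular contact is a (protein atom, ligand atom) pair typed by the
pair of their atom types and binned by their distance into half-open shells
``(d1, d2]``.  The count matrix

    F[m, k] = #{ (i, j) : (type_i^P, type_j^L) = pair_m  and  d_ij in shell_k }

is the OnionNet-style representation; the contact profile adds, per cell,
the mean pair distance (0 by convention for empty cells, since the mean of
no distances is undefined).

IMC pair types are ordered row-major, protein type major:
``m = index(protein type) * |ligand alphabet| + index(ligand type)``.
Both representations depend only on interatomic distances and per-atom
types, hence are invariant under rigid motions and atom reordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .complex_model import (
    AtomTypeScheme,
    MolecularComplex,
    ShellScheme,
    assign_types,
    onionnet_atom_types,
    pairwise_distances,
)

logger = logging.getLogger("plbap")

__all__ = [
    "IMCTypeIndex",
    "IMCMatrix",
    "IMCProfile",
    "onionnet_shells",
    "count_contacts",
    "profile_contacts",
    "imc_matrix_to_frame",
]


@dataclass(frozen=True)
class IMCTypeIndex:
    """Row-major crossing of a protein and a ligand atom-type alphabet."""

    protein_scheme: AtomTypeScheme
    ligand_scheme: AtomTypeScheme

    @classmethod
    def onionnet(cls) -> "IMCTypeIndex":
        scheme = onionnet_atom_types()
        return cls(protein_scheme=scheme, ligand_scheme=scheme)

    @property
    def n_pairs(self) -> int:
        return len(self.protein_scheme) * len(self.ligand_scheme)

    @property
    def pair_labels(self) -> list[str]:
        return [f"P:{p}|L:{l}" for p in self.protein_scheme.alphabet
                for l in self.ligand_scheme.alphabet]

    def pair_index(self, protein_label: str, ligand_label: str) -> int:
        return (self.protein_scheme.index_of(protein_label) * len(self.ligand_scheme)
                + self.ligand_scheme.index_of(ligand_label))


@dataclass(frozen=True)
class IMCMatrix:
    """``counts``: M x K nonnegative integer contact-count matrix."""

    counts: np.ndarray


@dataclass(frozen=True)
class IMCProfile:
    """``values``: M x K x 2 array; channel 0 = count, channel 1 = mean
    pair distance in angstrom (0 for empty cells)."""

    values: np.ndarray


def onionnet_shells() -> ShellScheme:
    """The 60-shell scheme: first shell (0, 1], then 59 shells of width 0.5 A.

    The intervals end at 30.5 A; the commonly quoted "0 to 30 A" span is an
    approximation of this construction.
    """
    edges = [0.0, 1.0] + [1.0 + 0.5 * k for k in range(1, 60)]
    return ShellScheme(tuple(edges))


def _pair_bins(complex_: MolecularComplex, index: IMCTypeIndex,
               shells: ShellScheme) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flattened (pair-type m, shell k, distance) arrays for in-range pairs.

    Protein atoms farther than the outermost shell boundary from every
    ligand atom are pre-filtered; the result is identical to the full
    double loop because such atoms cannot land in any shell.
    """
    protein, ligand = complex_.protein, complex_.ligand
    if len(protein) == 0:
        logger.warning("%s: no protein atoms; IMC matrix is all zeros",
                       complex_.identifier)
        empty = np.zeros(0, dtype=int)
        return empty, empty, np.zeros(0)
    p_types = np.array([index.protein_scheme.index_of(t)
                        for t in assign_types(protein, index.protein_scheme)])
    l_types = np.array([index.ligand_scheme.index_of(t)
                        for t in assign_types(ligand, index.ligand_scheme)])
    d = pairwise_distances(protein.coords, ligand.coords)
    near = d.min(axis=1) <= shells.outer
    d = d[near]
    p_types = p_types[near]
    shell_idx = shells.bin_indices(d)
    in_range = shell_idx >= 0
    pi, li = np.nonzero(in_range)
    m = p_types[pi] * len(index.ligand_scheme) + l_types[li]
    return m, shell_idx[pi, li], d[pi, li]


def count_contacts(complex_: MolecularComplex, index: IMCTypeIndex,
                   shells: ShellScheme) -> IMCMatrix:
    """Contact-count matrix F[m, k]; its total equals the number of
    protein-ligand pairs inside the union of shells."""
    m, k, _ = _pair_bins(complex_, index, shells)
    counts = np.zeros((index.n_pairs, shells.n_shells), dtype=np.int64)
    np.add.at(counts, (m, k), 1)
    return IMCMatrix(counts)


def profile_contacts(complex_: MolecularComplex, index: IMCTypeIndex,
                     shells: ShellScheme) -> IMCProfile:
    """Count + mean-distance profile per (pair type, shell) cell."""
    m, k, d = _pair_bins(complex_, index, shells)
    counts = np.zeros((index.n_pairs, shells.n_shells))
    sums = np.zeros_like(counts)
    np.add.at(counts, (m, k), 1.0)
    np.add.at(sums, (m, k), d)
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return IMCProfile(np.stack([counts, means], axis=-1))


def imc_matrix_to_frame(matrix: IMCMatrix | IMCProfile, index: IMCTypeIndex):
    """Counts as a labeled DataFrame (rows ``P:C|L:O`` style, columns
    ``s1..sK``) ready for CSV export."""
    import pandas as pd

    values = matrix.counts if isinstance(matrix, IMCMatrix) else matrix.values[:, :, 0]
    columns = [f"s{k + 1}" for k in range(values.shape[1])]
    return pd.DataFrame(values, index=index.pair_labels, columns=columns)
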