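"""Atomic-environment tensors and radial pooling.

The atomic-convolution representation describes each atom ``i`` of a
structure by the distances to its ``M`` nearest spatial neighbors, scattered
into ``K`` atom-type channels:

    T[i, j, k] = ||C_i - C_{i_j}||   if the j-th nearest neighbor of atom i
                                     has type omega_k, else 0.

A bank of radial filters then pools the neighbor axis into a fixed-size
``N x K x Q`` tensor:

    P[i, k, q] = sum_j f_q(T[i, j, k])
    f_q(x) = 1/2 * exp(-(x - r_q)^2 / sigma_q^2) * (cos(pi x / R_c) + 1)
             for 0 < x < R_c, else 0.

Zero tensor entries (missing neighbor or other-type channel) contribute
nothing, because ``f_q`` is defined to vanish outside ``0 < x < R_c``.
Both tensors depend on coordinates only through interatomic distances and
are therefore invariant under rigid motions of the whole structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .complex_model import (
    AtomTypeScheme,
    MolecularComplex,
    Molecule,
    ValidationError,
    assign_types,
)

__all__ = [
    "AtomEnvTensor",
    "RadialFilterBank",
    "PooledEnvTensor",
    "build_filter_centers",
    "build_atom_env_tensor",
    "radial_pool",
    "radial_filter",
    "featurize_thermodynamic_cycle",
]


@dataclass(frozen=True)
class AtomEnvTensor:
    """``values``: N x M x K distance tensor; ``neighbor_index``: N x M table
    of neighbor atom ids (-1 for missing slots)."""

    values: np.ndarray
    neighbor_index: np.ndarray
    scheme_name: str

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]

    @property
    def n_neighbors(self) -> int:
        return self.values.shape[1]

    @property
    def n_types(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class RadialFilterBank:
    """Fixed radial filters: centers ``r_q`` (A), a shared width
    ``sigma_sq`` (A^2) and the hard cutoff ``R_c`` (A)."""

    centers: tuple[float, ...]
    sigma_sq: float
    cutoff: float

    def __post_init__(self) -> None:
        if self.sigma_sq <= 0:
            raise ValidationError("sigma_sq must be positive")
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if any(not (0 <= r < self.cutoff) for r in self.centers):
            raise ValidationError("filter centers must satisfy 0 <= r_q < R_c")

    @property
    def n_filters(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class PooledEnvTensor:
    """``values``: N x K x Q pooled (dimensionless) environment tensor."""

    values: np.ndarray


def build_filter_centers(cutoff: float, spacing: float) -> tuple[float, ...]:
    """Evenly spaced centers ``{0, s, 2s, ...}`` strictly below the cutoff.

    With ``R_c = 12`` a 2 A spacing gives the six centers 0..10 and a 4 A
    spacing the three centers 0, 4, 8; a spacing at or beyond the cutoff
    degenerates to the single center 0.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    centers = []
    r = 0.0
    while r < cutoff:
        centers.append(r)
        r += spacing
    return tuple(centers) if centers else (0.0,)


def _atoms_of(source: Molecule | MolecularComplex) -> tuple[np.ndarray, list[str], str]:
    if isinstance(source, MolecularComplex):
        coords = np.vstack([source.protein.coords, source.ligand.coords])
        atoms = source.protein.atoms + source.ligand.atoms
    else:
        coords = source.coords
        atoms = source.atoms
    return coords, atoms, type(source).__name__


def build_atom_env_tensor(source: Molecule | MolecularComplex, n_neighbors: int,
                          scheme: AtomTypeScheme) -> AtomEnvTensor:
    """Build the N x M x K neighbor-distance tensor.

    Neighbors are the M nearest atoms (self excluded, search unrestricted by
    the pooling cutoff), ties broken by ascending atom index; structures with
    fewer than M+1 atoms leave the trailing slots all-zero with neighbor
    index -1.
    """
    if n_neighbors < 1:
        raise ValidationError("n_neighbors must be >= 1")
    coords, atoms, _ = _atoms_of(source)
    n = len(atoms)
    k_types = len(scheme)
    values = np.zeros((n, n_neighbors, k_types))
    neighbor_index = np.full((n, n_neighbors), -1, dtype=int)
    if n <= 1:
        warnings.warn("atomic-environment tensor of a single-atom input is all zeros")
        return AtomEnvTensor(values, neighbor_index, scheme.name)

    labels = [scheme.match(a) for a in atoms]
    type_idx = np.array([scheme.index_of(lb) for lb in labels])
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    # stable argsort on distance => equal distances fall back to atom index
    order = np.argsort(d, axis=1, kind="stable")[:, :n_neighbors]
    m_eff = min(n_neighbors, n - 1)
    rows = np.repeat(np.arange(n), m_eff)
    cols = np.tile(np.arange(m_eff), n)
    nbr = order[:, :m_eff].ravel()
    neighbor_index[rows, cols] = nbr
    values[rows, cols, type_idx[nbr]] = d[rows, nbr]
    return AtomEnvTensor(values, neighbor_index, scheme.name)


def radial_filter(x: np.ndarray, center: float, sigma_sq: float,
                  cutoff: float) -> np.ndarray:
    """The pooling kernel f_q; zero outside the open interval (0, R_c)."""
    x = np.asarray(x, float)
    inside = (x > 0) & (x < cutoff)
    out = np.zeros_like(x)
    xv = x[inside]
    out[inside] = 0.5 * np.exp(-(xv - center) ** 2 / sigma_sq) * (
        np.cos(np.pi * xv / cutoff) + 1.0)
    return out


def radial_pool(env: AtomEnvTensor, bank: RadialFilterBank) -> PooledEnvTensor:
    """Pool the neighbor axis: P[i, k, q] = sum_j f_q(T[i, j, k]).

    Every f_q value lies in [0, 1], so each pooled entry is bounded by the
    number of same-type neighbors inside the cutoff.
    """
    t = env.values  # (N, M, K)
    pooled = np.empty((t.shape[0], t.shape[2], bank.n_filters))
    for q, r_q in enumerate(bank.centers):
        pooled[:, :, q] = radial_filter(t, r_q, bank.sigma_sq, bank.cutoff).sum(axis=1)
    return PooledEnvTensor(pooled)


def featurize_thermodynamic_cycle(
    complex_: MolecularComplex, n_neighbors: int, scheme: AtomTypeScheme,
    bank: RadialFilterBank,
) -> dict[str, PooledEnvTensor]:
    """Pooled tensors for the three legs of the binding thermodynamic cycle
    (complex, protein alone, ligand alone) under one shared scheme/bank."""
    out = {}
    for key, source in (("complex", complex_), ("protein", complex_.protein),
                        ("ligand", complex_.ligand)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            env = build_atom_env_tensor(source, n_neighbors, scheme)
        out[key] = radial_pool(env, bank)
    return out
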