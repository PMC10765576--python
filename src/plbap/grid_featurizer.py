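"""Voxel-grid representation of a binding area.

A cubic lattice of side ``X`` angstrom and resolution ``r`` is centered on
the ligand's geometric center, giving ``G = round(X/r) + 1`` lattice points
per axis.  Each lattice point carries a feature vector of per-atom property
channels, filled by one of two strategies:

* ``contribution`` -- every atom contributes to every voxel with the
  distance weight ``1 - exp(-(r_vdw / d)^12)`` (defined as 1 at d = 0,
  its limit), times the atom's property value;
* ``aggregate`` -- each atom deposits its property values in the single
  nearest lattice point (ties resolved to the lower index; atoms outside
  the extent are ignored).

A ``single`` layout fills one channel block from all atoms; the
``two_grid`` layout stacks protein channels then ligand channels.  Since
the lattice rides on the ligand center, grids are translation invariant;
they are not rotation invariant, which is why right-angle rotation
augmentation (4 quarter-turns about z, or all 24 cube rotations) is
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .complex_model import MolecularComplex, Molecule, ValidationError

__all__ = [
    "KDEEP_CHANNELS",
    "GridSpec",
    "VoxelGrid",
    "ligand_center",
    "fill_grid",
    "fill_contribution",
    "fill_aggregate",
    "augment_rotations",
    "cube_rotations",
    "atom_property",
]

#: The 8 per-role channels of the two-grid layout.
KDEEP_CHANNELS = (
    "hydrophobic", "aromatic", "hbond_donor", "hbond_acceptor",
    "pos_ionizable", "neg_ionizable", "metallic", "excluded_volume",
)


def atom_property(atom, name: str) -> float:
    """Numeric value of a named channel property for one atom.

    ``excluded_volume`` is occupancy (1 per atom); boolean flags map to
    0/1; any scalar atom attribute (e.g. ``partial_charge``) is passed
    through.
    """
    if name == "excluded_volume":
        return 1.0
    if name in atom.flags:
        return float(atom.flags[name])
    value = getattr(atom, name, None)
    if value is None:
        raise ValidationError(f"unknown channel property {name!r}")
    return float(value)


@dataclass(frozen=True)
class GridSpec:
    """Cubic grid geometry and channel layout.

    ``extent`` is the full side length X (A), ``resolution`` the lattice
    spacing r (A); lattice points span [-X/2, +X/2] per axis relative to the
    ligand center, so ``points_per_side = round(X/r) + 1`` (a 20 A grid at
    1 A resolution has 21 points per side).  A ``cells_mode`` grid instead
    uses ``round(X/r)`` cell centers per axis, the convention of tools that
    count cells rather than lattice points.
    """

    extent: float = 20.0
    resolution: float = 1.0
    layout: str = "two_grid"  # or "single"
    channels: tuple[str, ...] = KDEEP_CHANNELS
    cells_mode: bool = False

    def __post_init__(self) -> None:
        if self.extent <= 0 or self.resolution <= 0:
            raise ValidationError("extent and resolution must be positive")
        if self.layout not in ("single", "two_grid"):
            raise ValidationError(f"unknown layout {self.layout!r}")

    @property
    def points_per_side(self) -> int:
        n = round(self.extent / self.resolution)
        return n if self.cells_mode else n + 1

    @property
    def n_channels(self) -> int:
        return len(self.channels) * (2 if self.layout == "two_grid" else 1)

    def axis_coords(self) -> np.ndarray:
        """Lattice point coordinates along one axis, relative to center."""
        g = self.points_per_side
        if self.cells_mode:
            # cell centers: offset half a cell from the boundary
            start = -self.extent / 2 + self.resolution / 2
        else:
            start = -self.extent / 2
        return start + self.resolution * np.arange(g)


@dataclass(frozen=True)
class VoxelGrid:
    """``values``: G x G x G x C feature tensor (protein channels first in
    the two-grid layout)."""

    values: np.ndarray
    spec: GridSpec = field(compare=False)


def ligand_center(complex_: MolecularComplex) -> np.ndarray:
    """Unweighted mean of ligand atom coordinates (the grid center)."""
    if len(complex_.ligand) == 0:
        raise ValidationError("ligand is empty")
    return complex_.ligand.coords.mean(axis=0)


def _role_blocks(complex_: MolecularComplex, spec: GridSpec):
    """(molecule, channel offset) blocks to fill for the chosen layout."""
    if spec.layout == "two_grid":
        return [(complex_.protein, 0), (complex_.ligand, len(spec.channels))]
    return [(complex_.protein, 0), (complex_.ligand, 0)]


def _property_matrix(molecule: Molecule, channels: tuple[str, ...]) -> np.ndarray:
    return np.array([[atom_property(a, name) for name in channels]
                     for a in molecule.atoms])


def fill_contribution(complex_: MolecularComplex, spec: GridSpec,
                      rotation: np.ndarray | None = None) -> VoxelGrid:
    """Distance-contribution filling: every atom adds
    ``(1 - exp(-(r_vdw/d)^12)) * p`` to every voxel's channels."""
    center = ligand_center(complex_)
    axis = spec.axis_coords()
    g = spec.points_per_side
    lattice = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"),
                       axis=-1).reshape(-1, 3)
    values = np.zeros((g, g, g, spec.n_channels))
    for molecule, offset in _role_blocks(complex_, spec):
        if len(molecule) == 0:
            continue
        rel = molecule.coords - center
        if rotation is not None:
            rel = rel @ np.asarray(rotation, float).T
        d = cdist(rel, lattice)  # (n_atoms, G^3)
        rvdw = np.array([a.vdw_radius for a in molecule.atoms])[:, None]
        with np.errstate(divide="ignore"):
            weight = 1.0 - np.exp(-((rvdw / d) ** 12))
        weight[d == 0] = 1.0  # limiting value of the kernel
        props = _property_matrix(molecule, spec.channels)  # (n_atoms, C_role)
        block = (weight.T @ props).reshape(g, g, g, len(spec.channels))
        values[..., offset:offset + len(spec.channels)] += block
    return VoxelGrid(values, spec)


def fill_aggregate(complex_: MolecularComplex, spec: GridSpec,
                   rotation: np.ndarray | None = None) -> VoxelGrid:
    """Nearest-lattice-point aggregation: each atom's property vector is
    summed into its closest voxel; atoms outside the extent are ignored."""
    center = ligand_center(complex_)
    axis = spec.axis_coords()
    g = spec.points_per_side
    values = np.zeros((g, g, g, spec.n_channels))
    half = spec.extent / 2
    for molecule, offset in _role_blocks(complex_, spec):
        if len(molecule) == 0:
            continue
        rel = molecule.coords - center
        if rotation is not None:
            rel = rel @ np.asarray(rotation, float).T
        inside = np.all(np.abs(rel) <= half, axis=1)
        if not inside.any():
            continue
        rel_in = rel[inside]
        # nearest lattice index; exact midpoints resolve to the lower index
        frac = (rel_in - axis[0]) / spec.resolution
        idx = np.ceil(frac - 0.5).astype(int)
        idx = np.clip(idx, 0, g - 1)
        props = _property_matrix(molecule, spec.channels)[inside]
        c_slice = slice(offset, offset + len(spec.channels))
        np.add.at(values[..., c_slice], (idx[:, 0], idx[:, 1], idx[:, 2]), props)
    return VoxelGrid(values, spec)


def fill_grid(complex_: MolecularComplex, spec: GridSpec,
              strategy: str = "contribution",
              rotation: np.ndarray | None = None) -> VoxelGrid:
    if strategy == "contribution":
        return fill_contribution(complex_, spec, rotation)
    if strategy == "aggregate":
        return fill_aggregate(complex_, spec, rotation)
    raise ValidationError(f"unknown filling strategy {strategy!r}")


def _z_quarter_turns() -> list[np.ndarray]:
    r = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
    mats = [np.eye(3)]
    for _ in range(3):
        mats.append(r @ mats[-1])
    return mats


def cube_rotations(n: int) -> list[np.ndarray]:
    """The 4 z-axis quarter turns or all 24 rotations of the cube group,
    as exact signed permutation matrices."""
    if n == 4:
        return _z_quarter_turns()
    if n == 24:
        mats = []
        for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
            for signs in np.ndindex(2, 2, 2):
                m = np.zeros((3, 3))
                for row, col in enumerate(perm):
                    m[row, col] = (-1.0) ** signs[row]
                if round(np.linalg.det(m)) == 1:
                    mats.append(m)
        return mats
    raise ValidationError("n_rotations must be 4 or 24")


def augment_rotations(complex_: MolecularComplex, spec: GridSpec,
                      n_rotations: int,
                      strategy: str = "contribution") -> list[VoxelGrid]:
    """Right-angle rotation augmentation: each grid is filled after rotating
    the atom coordinates about the grid center by one element of the cube
    rotation group (first element = identity)."""
    return [fill_grid(complex_, spec, strategy, rotation=rot)
            for rot in cube_rotations(n_rotations)]
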