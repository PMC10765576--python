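"""Protein-ligand complex data model, structure I/O, atom typing and cropping.

A complex is two molecules -- a protein and a ligand -- each an ordered list
of atoms with Cartesian coordinates (angstrom) plus a covalent bond list.
Binding affinity, when known, is stored as -log K_d/i.  All downstream
feature representations (atomic-environment tensors, intermolecular-contact
matrices, voxel grids, binding-site graphs) are built from this model.

Distance conventions used throughout the package:

* shell intervals are half-open ``(low, high]``;
* binding-site cropping keeps protein atoms at distance ``<= cutoff``;
* atom indices are 0-based.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("plbap")

__all__ = [
    "PLBAPError",
    "FormatError",
    "ValidationError",
    "Atom",
    "Molecule",
    "MolecularComplex",
    "AtomTypeScheme",
    "ShellScheme",
    "PHARMACOPHORE_FLAGS",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "onionnet_atom_types",
    "acnn_atom_types",
    "read_complex",
    "read_ligand",
    "read_protein_pdb",
    "write_pdb",
    "write_sdf",
    "assign_properties",
    "assign_types",
    "crop_binding_site",
    "pairwise_distances",
    "infer_bonds",
]


class PLBAPError(Exception):
    """Base class for package errors."""


class FormatError(PLBAPError):
    """A structure file does not parse under its declared standard."""


class ValidationError(PLBAPError):
    """Inputs violate a documented precondition."""


#: Boolean pharmacophore/property flags carried by every atom.
PHARMACOPHORE_FLAGS = (
    "hydrophobic",
    "aromatic",
    "hbond_donor",
    "hbond_acceptor",
    "ring_member",
    "pos_ionizable",
    "neg_ionizable",
    "metallic",
)

# Van der Waals radii in angstrom (Bondi/Alvarez consensus values for the
# elements common in protein-ligand complexes).  Unknown elements fall back
# to DEFAULT_VDW_RADIUS with a logged warning.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Na": 2.27, "Mg": 1.73, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "K": 2.75, "Ca": 2.31, "Mn": 2.05, "Fe": 2.04, "Co": 2.00,
    "Ni": 1.97, "Cu": 1.96, "Zn": 2.01, "Se": 1.90, "Br": 1.85,
    "Cd": 2.18, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70

METALS = {
    "Li", "Na", "K", "Rb", "Cs", "Mg", "Ca", "Sr", "Ba", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Cd", "Hg", "Al", "Ga",
}
HALOGENS = {"F", "Cl", "Br", "I", "At"}
WATER_RESNAMES = {"HOH", "WAT", "DOD", "TIP", "TIP3", "SOL"}

BOND_ORDERS = ("single", "double", "triple", "aromatic")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom: element, position and the per-atom properties used by the
    grid and graph featurizers."""

    index: int
    element: str
    coords: np.ndarray
    vdw_radius: float = DEFAULT_VDW_RADIUS
    partial_charge: float = 0.0
    is_hetero: bool = False
    hybridization: str = "other"  # sp / sp2 / sp3 / other
    heavy_neighbor_count: int = 0
    hetero_neighbor_count: int = 0
    flags: dict[str, bool] = field(
        default_factory=lambda: {name: False for name in PHARMACOPHORE_FLAGS}
    )

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.index}: coords must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValidationError(f"atom {self.index}: vdw_radius must be positive")
        if self.heavy_neighbor_count < 0 or self.hetero_neighbor_count < 0:
            raise ValidationError(f"atom {self.index}: neighbor counts must be >= 0")
        for name in PHARMACOPHORE_FLAGS:
            self.flags.setdefault(name, False)


@dataclass
class Molecule:
    """An ordered atom list plus covalent bonds; ``role`` is protein or ligand.

    Bonds are stored once per pair as ``(i, j, order)`` with ``i < j``.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    role: str = "ligand"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        canon: list[tuple[int, int, str]] = []
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValidationError(f"bond ({i},{j}) has invalid endpoints for {n} atoms")
            if order not in BOND_ORDERS:
                raise ValidationError(f"unknown bond order {order!r}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValidationError(f"duplicate bond {key}")
            seen.add(key)
            canon.append((key[0], key[1], order))
        self.bonds = canon

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in angstrom."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coords for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def bond_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.bonds}

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in self.atoms]
        for i, j, _ in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Molecule":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
        tr = np.zeros(3) if translation is None else np.asarray(translation, float)
        atoms = [replace(a, coords=rot @ a.coords + tr, flags=dict(a.flags))
                 for a in self.atoms]
        return Molecule(atoms=atoms, bonds=list(self.bonds), role=self.role)


@dataclass
class MolecularComplex:
    """A protein-ligand pair with an optional affinity label (-log K_d/i)."""

    identifier: str
    protein: Molecule
    ligand: Molecule
    affinity: float | None = None

    def __post_init__(self) -> None:
        if len(self.ligand) == 0:
            raise ValidationError(f"{self.identifier}: ligand is empty")
        if self.affinity is not None and not math.isfinite(self.affinity):
            raise ValidationError(f"{self.identifier}: affinity must be finite")

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "MolecularComplex":
        return MolecularComplex(
            identifier=self.identifier,
            protein=self.protein.transformed(rotation, translation),
            ligand=self.ligand.transformed(rotation, translation),
            affinity=self.affinity,
        )


@dataclass(frozen=True)
class AtomTypeScheme:
    """An ordered atom-type alphabet with a total matching rule.

    ``matcher`` maps an :class:`Atom` to exactly one label of ``alphabet``;
    unmatched elements go to the scheme's catch-all label.
    """

    name: str
    alphabet: tuple[str, ...]
    matcher: Callable[[Atom], str]

    def __post_init__(self) -> None:
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValidationError(f"scheme {self.name}: duplicate labels in alphabet")

    def __len__(self) -> int:
        return len(self.alphabet)

    def match(self, atom: Atom) -> str:
        label = self.matcher(atom)
        if label not in self.alphabet:
            raise ValidationError(
                f"scheme {self.name}: matcher returned {label!r} outside alphabet")
        return label

    def index_of(self, label: str) -> int:
        return self.alphabet.index(label)


def _element_table_matcher(table: frozenset[str], halogen_label: str | None,
                           catch_all: str) -> Callable[[Atom], str]:
    def matcher(atom: Atom) -> str:
        el = atom.element
        if el in table:
            return el
        if halogen_label is not None and el in HALOGENS:
            return halogen_label
        return catch_all
    return matcher


def onionnet_atom_types() -> AtomTypeScheme:
    """The 8-letter alphabet {C, N, O, H, P, S, HAX, Du}: named elements map
    to themselves, any halogen to HAX, everything else to the dummy type Du."""
    table = frozenset({"C", "N", "O", "H", "P", "S"})
    return AtomTypeScheme(
        name="onionnet8",
        alphabet=("C", "N", "O", "H", "P", "S", "HAX", "Du"),
        matcher=_element_table_matcher(table, "HAX", "Du"),
    )


def acnn_atom_types() -> AtomTypeScheme:
    """The 15-type element alphabet (C, N, O, F, Na, Mg, P, S, Cl, Ca, Mn,
    Zn, Br, I) with a single catch-all for every other element."""
    elements = ("C", "N", "O", "F", "Na", "Mg", "P", "S", "Cl", "Ca",
                "Mn", "Zn", "Br", "I")
    return AtomTypeScheme(
        name="acnn15",
        alphabet=elements + ("other",),
        matcher=_element_table_matcher(frozenset(elements), None, "other"),
    )


@dataclass(frozen=True)
class ShellScheme:
    """Ordered, contiguous half-open distance intervals ``(low, high]``.

    Stored as the sorted edge vector ``[b0, b1, ..., bK]``; shell ``k``
    (0-based) is ``(b_k, b_{k+1}]``.
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, float)
        if e.size < 2:
            raise ValidationError("shell scheme needs at least two edges")
        if e[0] < 0:
            raise ValidationError("first shell boundary must be >= 0")
        if not np.all(np.diff(e) > 0):
            raise ValidationError("shell edges must be strictly increasing")

    @classmethod
    def from_intervals(cls, intervals: Sequence[tuple[float, float]]) -> "ShellScheme":
        edges = [intervals[0][0]]
        for lo, hi in intervals:
            if not math.isclose(lo, edges[-1]):
                raise ValidationError("shell intervals must be contiguous")
            edges.append(hi)
        return cls(tuple(edges))

    @property
    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.edges[:-1], self.edges[1:]))

    @property
    def n_shells(self) -> int:
        return len(self.edges) - 1

    @property
    def outer(self) -> float:
        return self.edges[-1]

    def bin_indices(self, distances: np.ndarray) -> np.ndarray:
        """Shell index per distance (-1 when outside every shell).

        A distance equal to an upper boundary belongs to the lower shell,
        matching the ``(low, high]`` convention.
        """
        d = np.asarray(distances, float)
        idx = np.searchsorted(self.edges, d, side="left") - 1
        idx[(d <= self.edges[0]) | (d > self.edges[-1])] = -1
        return idx


# ---------------------------------------------------------------------------
# structure file I/O
# ---------------------------------------------------------------------------

def read_protein_pdb(path: str | Path, keep_waters: bool = False) -> Molecule:
    """Read a protein (plus non-water HETATM groups) from a PDB file.

    Waters are dropped by default and the dropped count is logged.  Covalent
    bonds come from CONECT records when present, otherwise from an
    element-dependent distance rule (heavy-heavy < 1.8 A, X-H < 1.2 A).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"{path}: malformed PDB record ({exc})") from exc

    atoms: list[Atom] = []
    serial_map: dict[int, int] = {}
    n_waters = 0
    for residue in structure[0].get_residues():
        hetfield = residue.id[0]
        is_water = hetfield == "W" or residue.get_resname().strip() in WATER_RESNAMES
        if is_water and not keep_waters:
            n_waters += len(residue)
            continue
        for bio_atom in residue.get_atoms():
            element = (bio_atom.element or "").strip().capitalize()
            if not element:
                element = "".join(c for c in bio_atom.get_name() if c.isalpha())[:1]
            idx = len(atoms)
            serial_map[bio_atom.get_serial_number()] = idx
            atoms.append(Atom(
                index=idx,
                element=element,
                coords=np.asarray(bio_atom.coord, float),
                vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
                is_hetero=hetfield != " ",
            ))
    if n_waters:
        logger.info("%s: dropped %d water atoms", path.name, n_waters)

    bonds = _read_conect_bonds(path, serial_map)
    mol = Molecule(atoms=atoms, bonds=bonds, role="protein")
    if not bonds:
        mol.bonds = infer_bonds(mol)
    return mol


def _read_conect_bonds(path: Path, serial_map: dict[int, int]) -> list[tuple[int, int, str]]:
    pairs: set[tuple[int, int]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("CONECT"):
                continue
            fields = [line[6:11], line[11:16], line[16:21], line[21:26], line[26:31]]
            serials = [int(f) for f in fields if f.strip()]
            if not serials:
                continue
            a = serial_map.get(serials[0])
            for s in serials[1:]:
                b = serial_map.get(s)
                if a is not None and b is not None and a != b:
                    pairs.add((min(a, b), max(a, b)))
    return [(i, j, "single") for i, j in sorted(pairs)]


def infer_bonds(molecule: Molecule,
                heavy_cutoff: float = 1.8,
                hydrogen_cutoff: float = 1.2) -> list[tuple[int, int, str]]:
    """Distance-rule covalent bond perception: heavy-heavy pairs below
    ``heavy_cutoff``, heavy-H pairs below ``hydrogen_cutoff``, no H-H bonds."""
    coords = molecule.coords
    if len(coords) < 2:
        return []
    is_h = np.array([a.element == "H" for a in molecule.atoms])
    d = cdist(coords, coords)
    bonds: list[tuple[int, int, str]] = []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            if is_h[i] and is_h[j]:
                continue
            cutoff = hydrogen_cutoff if (is_h[i] or is_h[j]) else heavy_cutoff
            if 0 < d[i, j] < cutoff:
                bonds.append((i, j, "single"))
    return bonds


_RDKIT_BOND_ORDERS = {"SINGLE": "single", "DOUBLE": "double",
                      "TRIPLE": "triple", "AROMATIC": "aromatic"}


def read_ligand(path: str | Path) -> Molecule:
    """Read a ligand from SDF or MOL2 (by extension), bonds from the file's
    bond block, hydrogens retained."""
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        mol = next(iter(supplier), None)
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    else:
        raise FormatError(f"{path}: unsupported ligand format {suffix!r} (need .sdf or .mol2)")
    if mol is None:
        raise FormatError(f"{path}: ligand file failed to parse as {suffix[1:].upper()}")
    if mol.GetNumAtoms() == 0:
        raise ValidationError(f"{path}: ligand has no atoms")
    if mol.GetNumConformers() == 0:
        raise FormatError(f"{path}: ligand has no 3D coordinates")

    conf = mol.GetConformer()
    atoms = []
    for i, rd_atom in enumerate(mol.GetAtoms()):
        element = rd_atom.GetSymbol()
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(
            index=i,
            element=element,
            coords=np.array([pos.x, pos.y, pos.z]),
            vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
        ))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
         _RDKIT_BOND_ORDERS.get(str(b.GetBondType()), "single"))
        for b in mol.GetBonds()
    ]
    return Molecule(atoms=atoms, bonds=bonds, role="ligand")


def read_complex(protein_path: str | Path, ligand_path: str | Path,
                 identifier: str | None = None,
                 affinity: float | None = None) -> MolecularComplex:
    """Read a protein PDB and a ligand SDF/MOL2 into one complex."""
    protein = read_protein_pdb(protein_path)
    ligand = read_ligand(ligand_path)
    if identifier is None:
        identifier = Path(protein_path).stem
    return MolecularComplex(identifier=identifier, protein=protein,
                            ligand=ligand, affinity=affinity)


def write_pdb(molecule: Molecule, path: str | Path, resname: str = "MOL") -> Path:
    """Write atoms as fixed-column ATOM/HETATM records plus CONECT bonds."""
    path = Path(path)
    lines = []
    for k, atom in enumerate(molecule.atoms, start=1):
        record = "HETATM" if atom.is_hetero else "ATOM  "
        name = f"{atom.element}{k % 1000}"[:4]
        x, y, z = atom.coords
        lines.append(
            f"{record}{k:5d} {name:<4s} {resname:<3s} A{1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2s}"
        )
    for i, j, _ in molecule.bonds:
        lines.append(f"CONECT{i + 1:5d}{j + 1:5d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_sdf(molecule: Molecule, path: str | Path, name: str = "ligand") -> Path:
    """Write a molecule as an SDF V2000 file via RDKit."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for atom in molecule.atoms:
        rd_atom = Chem.Atom(atom.element)
        rd_atom.SetNoImplicit(True)
        rw.AddAtom(rd_atom)
    order_map = {"single": Chem.BondType.SINGLE, "double": Chem.BondType.DOUBLE,
                 "triple": Chem.BondType.TRIPLE, "aromatic": Chem.BondType.AROMATIC}
    for i, j, order in molecule.bonds:
        rw.AddBond(i, j, order_map[order])
    conf = Chem.Conformer(len(molecule.atoms))
    for i, atom in enumerate(molecule.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, atom.coords)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.SetProp("_Name", name)
    mol.UpdatePropertyCache(strict=False)
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    writer.write(mol)
    writer.close()
    return path


# ---------------------------------------------------------------------------
# property assignment & typing
# ---------------------------------------------------------------------------

def assign_properties(molecule: Molecule, ruleset: str = "heuristic",
                      table: Sequence[dict] | None = None) -> Molecule:
    """Populate per-atom property fields in place (and return the molecule).

    ``ruleset="heuristic"`` derives properties from elements and bonds with
    simple chemical rules (documented below); ``ruleset="fixture"`` copies a
    caller-supplied per-atom property ``table`` verbatim, so tests never
    depend on an external perception toolkit.

    Heuristic rules: neighbor counts from the bond graph; ring membership
    from cycle detection; aromatic = member of a ring whose bonds are all
    aromatic; donors are N/O/S bonded to H; acceptors are N/O/F; hydrophobic
    carbons/sulfurs have only C/S/H neighbors; positive-ionizable are
    nitrogens with >= 2 hydrogens; negative-ionizable are oxygens on a
    carbon bearing a second oxygen; metals from a fixed element set.
    Hybridization is a neighbor-count rule for C/N/O (aromatic -> sp2).
    """
    if ruleset == "fixture":
        if table is None:
            raise ValidationError("fixture ruleset requires a property table")
        if len(table) != len(molecule):
            raise ValidationError("property table length mismatch")
        for atom, props in zip(molecule.atoms, table):
            for key, value in props.items():
                if key in PHARMACOPHORE_FLAGS:
                    atom.flags[key] = bool(value)
                elif hasattr(atom, key):
                    setattr(atom, key, value)
                else:
                    raise ValidationError(f"unknown property {key!r} in fixture table")
        return molecule
    if ruleset != "heuristic":
        raise ValidationError(f"unknown property ruleset {ruleset!r}")

    nbrs = molecule.neighbor_lists()
    elements = molecule.elements
    ring_atoms, aromatic_atoms = _ring_membership(molecule)

    for i, atom in enumerate(molecule.atoms):
        el = atom.element
        if el not in VDW_RADII:
            logger.warning("element %r not in vdW table; using %.2f A",
                           el, DEFAULT_VDW_RADIUS)
        atom.vdw_radius = VDW_RADII.get(el, DEFAULT_VDW_RADIUS)
        neighbor_els = [elements[j] for j in nbrs[i]]
        heavy = [e for e in neighbor_els if e != "H"]
        atom.heavy_neighbor_count = len(heavy)
        atom.hetero_neighbor_count = sum(1 for e in heavy if e not in ("C", "H"))
        n_h = sum(1 for e in neighbor_els if e == "H")

        atom.flags["ring_member"] = i in ring_atoms
        atom.flags["aromatic"] = i in aromatic_atoms
        atom.flags["metallic"] = el in METALS
        atom.flags["hbond_donor"] = el in ("N", "O", "S") and n_h > 0
        atom.flags["hbond_acceptor"] = el in ("N", "O", "F")
        atom.flags["hydrophobic"] = el in ("C", "S") and all(
            e in ("C", "S", "H") for e in neighbor_els)
        atom.flags["pos_ionizable"] = el == "N" and n_h >= 2
        atom.flags["neg_ionizable"] = el == "O" and any(
            elements[j] == "C"
            and sum(1 for k in nbrs[j] if elements[k] == "O") >= 2
            for j in nbrs[i])

        if i in aromatic_atoms:
            atom.hybridization = "sp2"
        elif el == "C":
            total = len(neighbor_els)
            atom.hybridization = {4: "sp3", 3: "sp2", 2: "sp"}.get(total, "other")
        elif el in ("N", "O", "S"):
            atom.hybridization = "sp3"
        else:
            atom.hybridization = "other"
    return molecule


def _ring_membership(molecule: Molecule) -> tuple[set[int], set[int]]:
    """Atoms on any cycle, and atoms on a cycle made entirely of aromatic bonds."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(molecule)))
    order_of = {}
    for i, j, order in molecule.bonds:
        g.add_edge(i, j)
        order_of[(i, j)] = order
    ring_atoms: set[int] = set()
    aromatic_atoms: set[int] = set()
    for cycle in nx.cycle_basis(g):
        ring_atoms.update(cycle)
        edges = list(zip(cycle, cycle[1:] + cycle[:1]))
        if all(order_of.get((min(a, b), max(a, b))) == "aromatic" for a, b in edges):
            aromatic_atoms.update(cycle)
    return ring_atoms, aromatic_atoms


def assign_types(molecule: Molecule, scheme: AtomTypeScheme) -> list[str]:
    """One type label per atom under the scheme's (total) matching rule."""
    return [scheme.match(atom) for atom in molecule.atoms]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def pairwise_distances(coords_a: np.ndarray, coords_b: np.ndarray) -> np.ndarray:
    """Euclidean distance table (|A| x |B|) in angstrom."""
    a = np.atleast_2d(np.asarray(coords_a, float))
    b = np.atleast_2d(np.asarray(coords_b, float))
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("coordinates must be finite")
    return cdist(a, b)


def crop_binding_site(complex_: MolecularComplex, cutoff: float) -> MolecularComplex:
    """Keep all ligand atoms and the protein atoms within ``cutoff`` (inclusive)
    of any ligand atom; atom ordering and surviving bonds are preserved."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    protein = complex_.protein
    if len(protein) == 0:
        return complex_
    d_min = pairwise_distances(protein.coords, complex_.ligand.coords).min(axis=1)
    keep = np.flatnonzero(d_min <= cutoff)
    remap = {int(old): new for new, old in enumerate(keep)}
    atoms = [replace(protein.atoms[int(old)], index=new, flags=dict(protein.atoms[int(old)].flags))
             for new, old in enumerate(keep)]
    bonds = [(remap[i], remap[j], order) for i, j, order in protein.bonds
             if i in remap and j in remap]
    cropped = Molecule(atoms=atoms, bonds=bonds, role="protein")
    return MolecularComplex(identifier=complex_.identifier, protein=cropped,
                            ligand=complex_.ligand, affinity=complex_.affinity)
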