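"""Synthetic protein-ligand complexes and screening fixtures.

The generator emulates the geometry a pocket-bound ligand presents to the
featurizers: a compact ligand atom cluster (uniform in a ball at the
origin), a protein pocket shell around it (uniform between an inner and an
outer radius), organic element frequencies per role, a connected random
bond graph for the ligand, and an affinity label planted as a noisy linear
function of intermolecular-contact counts.  It makes no attempt at real
chemistry -- no valence rules, conformers or force fields -- so passing
tests demonstrate correctness of the featurization arithmetic, not
predictive power on crystal structures.

All randomness flows through an explicit seed; the same spec and seed
reproduce a complex bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .complex_model import (
    Atom,
    MolecularComplex,
    Molecule,
    ShellScheme,
    VDW_RADII,
    DEFAULT_VDW_RADIUS,
    ValidationError,
    assign_properties,
    write_pdb,
    write_sdf,
)
from .evaluation import ScoreTable
from .imc_featurizer import IMCTypeIndex, count_contacts

__all__ = [
    "ComplexGenSpec",
    "PlantedModelSpec",
    "generate_complex",
    "generate_complexes",
    "plant_affinity",
    "generate_screening_set",
    "write_fixture_files",
]

# Rough element frequencies of drug-like ligands (hydrogens included) and
# of protein pocket atoms.
DEFAULT_LIGAND_ELEMENTS = {
    "C": 0.42, "H": 0.38, "O": 0.09, "N": 0.07, "S": 0.02, "Cl": 0.02,
}
DEFAULT_PROTEIN_ELEMENTS = {
    "C": 0.32, "H": 0.47, "O": 0.12, "N": 0.08, "S": 0.01,
}


@dataclass(frozen=True)
class ComplexGenSpec:
    """Geometry and composition of one synthetic complex.

    Defaults mimic a drug-like ligand (24 atoms inside a 4 A ball) in a
    pocket shell of 120 protein atoms between 2 and 12 A from the ligand
    center, so that contacts populate many distance shells.
    """

    n_ligand_atoms: int = 24
    n_protein_atoms: int = 120
    ligand_radius: float = 4.0
    pocket_inner_radius: float = 2.0
    pocket_outer_radius: float = 12.0
    ligand_elements: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIGAND_ELEMENTS))
    protein_elements: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROTEIN_ELEMENTS))
    bond_density: float = 0.15  # extra ligand bonds per atom beyond the tree
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pocket_inner_radius >= self.pocket_outer_radius:
            raise ValidationError("pocket inner radius must be below outer")
        for freqs in (self.ligand_elements, self.protein_elements):
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValidationError("element frequencies must sum to 1")


@dataclass(frozen=True)
class PlantedModelSpec:
    """Sparse linear affinity model over contact-matrix cells.

    ``weights`` maps (pair-type index, shell index) cells to coefficients;
    the label is intercept + <weights, counts> + Normal(0, noise_sd^2).
    """

    weights: dict[tuple[int, int], float]
    intercept: float = 5.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("planted model needs at least one nonzero weight")


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return direction * r[:, None]


def _uniform_shell(rng: np.random.Generator, n: int, inner: float,
                   outer: float) -> np.ndarray:
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    u = rng.random(n)
    r = (inner ** 3 + u * (outer ** 3 - inner ** 3)) ** (1.0 / 3.0)
    return direction * r[:, None]


def _sample_atoms(rng: np.random.Generator, coords: np.ndarray,
                  frequencies: dict[str, float]) -> list[Atom]:
    elements = list(frequencies)
    probs = np.array([frequencies[e] for e in elements])
    chosen = rng.choice(len(elements), size=len(coords), p=probs / probs.sum())
    return [Atom(index=i, element=elements[c], coords=xyz,
                 vdw_radius=VDW_RADII.get(elements[c], DEFAULT_VDW_RADIUS))
            for i, (c, xyz) in enumerate(zip(chosen, coords))]


def _random_ligand_bonds(rng: np.random.Generator, n: int,
                         density: float) -> list[tuple[int, int, str]]:
    """A random spanning tree plus round(density * n) extra edges."""
    if n < 2:
        return []
    order = rng.permutation(n)
    bonds: set[tuple[int, int]] = set()
    for pos in range(1, n):
        a = int(order[pos])
        b = int(order[rng.integers(0, pos)])
        bonds.add((min(a, b), max(a, b)))
    extras = round(density * n)
    attempts = 0
    while extras > 0 and attempts < 50 * n:
        a, b = rng.integers(0, n, size=2)
        attempts += 1
        if a != b and (min(a, b), max(a, b)) not in bonds:
            bonds.add((min(int(a), int(b)), max(int(a), int(b))))
            extras -= 1
    return [(i, j, "single") for i, j in sorted(bonds)]


def generate_complex(spec: ComplexGenSpec,
                     identifier: str | None = None) -> MolecularComplex:
    """One synthetic complex, deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lig_coords = _uniform_ball(rng, spec.n_ligand_atoms, spec.ligand_radius)
    prot_coords = _uniform_shell(rng, spec.n_protein_atoms,
                                 spec.pocket_inner_radius,
                                 spec.pocket_outer_radius)
    ligand = Molecule(
        atoms=_sample_atoms(rng, lig_coords, spec.ligand_elements),
        bonds=_random_ligand_bonds(rng, spec.n_ligand_atoms, spec.bond_density),
        role="ligand",
    )
    protein = Molecule(
        atoms=_sample_atoms(rng, prot_coords, spec.protein_elements),
        bonds=[], role="protein",
    )
    assign_properties(ligand)
    assign_properties(protein)
    return MolecularComplex(
        identifier=identifier or f"synth-{spec.seed}",
        protein=protein, ligand=ligand,
    )


def generate_complexes(n: int, base_spec: ComplexGenSpec,
                       seed: int) -> list[MolecularComplex]:
    """n complexes with per-complex seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    out = []
    for k, s in enumerate(sub_seeds):
        spec = ComplexGenSpec(**{**base_spec.__dict__, "seed": int(s)})
        out.append(generate_complex(spec, identifier=f"synth-{seed}-{k}"))
    return out


def plant_affinity(complex_: MolecularComplex, model: PlantedModelSpec,
                   shells: ShellScheme, index: IMCTypeIndex,
                   rng: np.random.Generator) -> MolecularComplex:
    """Attach an affinity label that is linear in the complex's contact
    counts plus Gaussian noise; with noise_sd = 0 the label is exactly the
    deterministic linear functional of the contact matrix."""
    counts = count_contacts(complex_, index, shells).counts
    signal = sum(w * counts[m, k] for (m, k), w in model.weights.items())
    noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
    complex_.affinity = float(model.intercept + signal + noise)
    return complex_


def generate_screening_set(n_actives: int, n_decoys: int, shift: float,
                           noise_sd: float = 1.0, seed: int = 0
                           ) -> tuple[ScoreTable, ScoreTable]:
    """Structure-free screening fixture.

    Actives score ~ Normal(shift, noise_sd^2) and decoys ~ Normal(0,
    noise_sd^2); returns (actives table, decoy pool table) suitable for
    :func:`plbap.evaluation.enrichment_sweep`.
    """
    rng = np.random.default_rng(seed)
    active_scores = rng.normal(shift, noise_sd, size=n_actives)
    decoy_scores = rng.normal(0.0, noise_sd, size=n_decoys)
    actives = ScoreTable.from_records(
        ids=[f"active-{i}" for i in range(n_actives)],
        y_true=active_scores, y_pred=active_scores,
        is_active=[True] * n_actives)
    decoys = ScoreTable.from_records(
        ids=[f"decoy-{i}" for i in range(n_decoys)],
        y_true=decoy_scores, y_pred=decoy_scores,
        is_active=[False] * n_decoys)
    return actives, decoys


def write_fixture_files(complex_: MolecularComplex, directory: str | Path
                        ) -> tuple[Path, Path]:
    """Write the complex as a PDB (protein) + SDF (ligand) pair that
    round-trips through :func:`plbap.complex_model.read_complex` to
    PDB coordinate precision (1e-3 A)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pdb_path = write_pdb(complex_.protein,
                         directory / f"{complex_.identifier}_protein.pdb")
    sdf_path = write_sdf(complex_.ligand,
                         directory / f"{complex_.identifier}_ligand.sdf",
                         name=complex_.identifier)
    manifest = {
        "identifier": complex_.identifier,
        "n_protein_atoms": len(complex_.protein),
        "n_ligand_atoms": len(complex_.ligand),
        "affinity": complex_.affinity,
    }
    (directory / f"{complex_.identifier}.json").write_text(
        json.dumps(manifest, indent=2))
    return pdb_path, sdf_path
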