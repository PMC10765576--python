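"""Shared fixtures: small synthetic complexes and rigid-motion helpers."""

from __future__ import annotations

import numpy as np
import pytest

from plbap import ComplexGenSpec, generate_complex


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniform random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    translation = rng.uniform(-20, 20, size=3)
    return rot, translation


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240103)


@pytest.fixture
def small_complex():
    """A compact fixture complex: 10 ligand + 30 protein atoms."""
    spec = ComplexGenSpec(n_ligand_atoms=10, n_protein_atoms=30,
                          pocket_outer_radius=10.0, seed=7)
    return generate_complex(spec)


@pytest.fixture
def medium_complex():
    """Default study-size complex: 24 ligand + 120 protein atoms."""
    return generate_complex(ComplexGenSpec(seed=11))
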