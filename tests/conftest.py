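"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from qmmdock.fixtures import make_toy_complex
from qmmdock.partitioning import make_partition
from qmmdock.qm_engines import QMEngineSpec


@pytest.fixture(scope="session")
def toy():
    """Default rigid-pocket complex with verified native pose (seed 7)."""
    return make_toy_complex(7)


@pytest.fixture(scope="session")
def toy_metal():
    return make_toy_complex(11, with_metal=True)


@pytest.fixture(scope="session")
def toy_covalent():
    return make_toy_complex(13, with_covalent=True)


@pytest.fixture(scope="session")
def toy_long():
    """Four heavy atoms: has a heavy-atom torsion and a box-worthy size."""
    return make_toy_complex(5, ligand_size=4, n_pocket_residues=6)


@pytest.fixture()
def mirror_setup(toy):
    """(system, partition at scale 1, spec) for mirror-oracle checks."""
    system = toy.system.copy()
    part = make_partition(system, mode="lig", scale=1.0)
    spec = QMEngineSpec(method="mirror-mm", ps_charge=part.ps_net_charge)
    return system, part, spec


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation matrix from a seeded generator."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(
        rng.uniform(0, np.pi) * _unit(rng.normal(size=3))
    ).as_matrix()


def _unit(v):
    return v / np.linalg.norm(v)
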