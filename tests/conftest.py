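from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import consite as cs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


TINY_PDB = """\
HETNAM     ZN ZINC ION
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  HIS A   3       7.600   0.000   0.000  1.00  0.00           C
HETATM    4 ZN    ZN A 101       1.000   2.000   3.000  1.00  0.00          ZN
HETATM    5  O   HOH A 201       5.000   5.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def tiny_model() -> cs.StructureModel:
    return cs.parse_pdb(TINY_PDB, pdb_id="TINY")


@pytest.fixture(scope="session")
def small_family() -> cs.Family:
    """A modest family used by several integration tests."""
    spec = cs.FamilySpec(
        n_members=8, base_length=40, ca_noise=0.2, mutation_rate=0.1,
        planted_sites=(cs.PlantedSite("ZN-ZN", (0.0, 0.0, 12.0), 0.15, 1.0),),
        decoys_per_member=2, seed=5, apo_query=False)
    return cs.make_family(spec)


def random_rigid_transform(rng: np.random.Generator) -> cs.RigidTransform:
    from scipy.spatial.transform import Rotation

    return cs.RigidTransform(
        Rotation.random(rng=rng).as_matrix(), rng.uniform(-20, 20, size=3))
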