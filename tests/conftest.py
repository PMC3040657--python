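"""Shared fixtures: the built synthetic model and small helper structures."""

import numpy as np
import pytest

from unbend.cg_simulator import CgConfig, build_bent_model
from unbend.model_io import AtomicModel


@pytest.fixture(scope="session")
def bent_model():
    """Default bent two-chain model: (AtomicModel, CgTopology, DomainMap)."""
    return build_bent_model(CgConfig())


@pytest.fixture(scope="session")
def model(bent_model):
    return bent_model[0]


@pytest.fixture(scope="session")
def topology(bent_model):
    return bent_model[1]


@pytest.fixture(scope="session")
def domain_map(bent_model):
    return bent_model[2]


def make_atoms(positions, radii=None, roles=None, donor_links=None,
               names=None, chains=None, resids=None,
               hydrophobic=None) -> AtomicModel:
    """Small hand-built atom tables for geometry-level tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    serial = np.arange(1, n + 1, dtype=np.int64)
    return AtomicModel(
        serial=serial,
        name=np.array(names if names is not None else ["CA"] * n, dtype=object),
        resname=np.array(["GLY"] * n, dtype=object),
        resid=np.array(resids if resids is not None else np.arange(1, n + 1)),
        chain=np.array(chains if chains is not None else ["A"] * n, dtype=object),
        xyz=positions,
        radius=np.array(radii if radii is not None else [1.8] * n, dtype=float),
        role=np.array(roles if roles is not None else ["none"] * n, dtype=object),
        donor_link=np.array(donor_links if donor_links is not None
                            else [-1] * n, dtype=np.int64),
        hydrophobic=np.array(hydrophobic if hydrophobic is not None
                             else [False] * n, dtype=bool),
        element=np.array(["BEAD"] * n, dtype=object),
    )


@pytest.fixture
def atom_factory():
    return make_atoms
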