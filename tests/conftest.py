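import numpy as np
import pytest
from hypothesis import settings

import varstruct as vs

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def helix60():
    return vs.make_helix(60)


@pytest.fixture(scope="session")
def displaced_pair(helix60):
    """Helix with residues 30-40 rigidly displaced by a 5 Å vector (3,0,4)."""
    plan = vs.PerturbationPlan(segment=(30, 40), displacement=(3.0, 0.0, 4.0))
    mutant, expected = vs.apply_perturbation(
        helix60, plan, sites=(30, 35, 40), flank=5, neighbor_cutoff=8.0,
        reject_cutoff=2.0,
    )
    return helix60, mutant, expected


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_rigid(rng):
    """A random proper rotation + translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t


def transformed_model(model, R, t):
    coords = model.ca_array() @ R.T + t
    return vs.StructureModel(
        chain_id=model.chain_id,
        residues=tuple(
            vs.Residue(index=r.index, aa=r.aa, ca=tuple(coords[i]))
            for i, r in enumerate(model.residues)
        ),
    )
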