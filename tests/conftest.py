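import numpy as np
import pytest

from itermodel.synthetic import (FixtureSpec, RegionPerturbation, make_fixture,
                                 make_map, make_true_model)


@pytest.fixture(scope="session")
def helix_model():
    """50-residue ideal helix, deterministic."""
    return make_true_model(FixtureSpec(fold="helix", n_res=50, seed=0))


@pytest.fixture(scope="session")
def helix_map(helix_model):
    return make_map(helix_model, resolution=3.0, spacing=1.0)


@pytest.fixture(scope="session")
def two_domain_fixture():
    """Standard seeded two-domain fixture: (truth, prediction, map).

    Domain 1 carries mild noise, domain 2 a 1.5 A / 15 degree perturbation.
    """
    spec = FixtureSpec(
        fold="two_domain", n_res=25, seed=1, map_resolution=2.5,
        perturbations=[RegionPerturbation(rmsd=0.8),
                       RegionPerturbation(rmsd=1.5, rotation_deg=15.0)])
    return make_fixture(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
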