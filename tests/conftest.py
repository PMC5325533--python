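import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=20,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from aquabridge import fixtures  # noqa: E402
from aquabridge.fixtures import FixtureSpec, make_pocket  # noqa: E402


@pytest.fixture(scope="session")
def ligands():
    """All ligand templates, built once per session."""
    return {name: fixtures.make_ligand(name) for name in fixtures.LIGAND_SMILES}


@pytest.fixture(scope="session")
def pocket_bundle():
    """(pocket, ligand, planted_sites) for the default self-certified pocket."""
    return make_pocket(FixtureSpec(seed=3, ligand_template="acetamide", n_planted=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
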