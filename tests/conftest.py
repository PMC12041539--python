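import numpy as np
import pytest

from specgin import fixture_molecules, smiles_to_graph


@pytest.fixture(scope="session")
def fixture_graphs():
    """All in-repo fixture molecules, featurised once per session."""
    return [smiles_to_graph(s) for s, _ in fixture_molecules()]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
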