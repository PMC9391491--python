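import numpy as np
import pytest

from growthctrl import biosynthesis as bio
from growthctrl import fixtures


@pytest.fixture
def chain3():
    """3-AA chain root -> A -> B with explicit constants for hand checks."""
    net = bio.AANetwork(
        amino_acids=("GLU", "A", "B"),
        upstream={"GLU": frozenset(), "A": frozenset({"GLU"}), "B": frozenset({"A"})},
        root="GLU",
        loss_kind={"GLU": "none", "A": "reverse", "B": "degradation"})
    kin = bio.AAKinetics(
        kcat_f={"GLU": 2.0, "A": 1.0, "B": 0.5},
        kcat_loss={"GLU": 0.0, "A": 0.2, "B": 0.1},
        K_I={"GLU": 100.0, "A": 50.0, "B": 25.0},
        K_M_up={("A", "GLU"): 100.0, ("B", "A"): 50.0},
        K_M_loss={"A": 500.0, "B": 250.0})
    return net, kin


@pytest.fixture
def toy_fit_fixture():
    return fixtures.generate_toy_aa_network(fixtures.FixtureSpec(seed=7, n_aa=3))


@pytest.fixture(scope="session")
def default_cell():
    return fixtures.default_cell_config(seed=0)
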