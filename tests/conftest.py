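import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from picoevo import simulate as sim
from picoevo.model import EvoTree, PhyleticPattern, StrainMetadata


@pytest.fixture(scope="session")
def default_dataset():
    """One generator run at the default configuration, shared across tests."""
    return sim.simulate_dataset(sim.SimConfig(seed=11))


@pytest.fixture
def four_leaf_tree():
    return EvoTree.from_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.7):0.4);", "subs/site")


@pytest.fixture
def small_pattern():
    rng = np.random.default_rng(42)
    return PhyleticPattern(
        ["A", "B", "C", "D"],
        [f"f{i}" for i in range(12)],
        rng.integers(0, 2, (4, 12)),
    )


@pytest.fixture
def clade_metadata():
    return StrainMetadata(
        {
            "A": {"clade": "I", "sub_cluster": "5.1"},
            "B": {"clade": "I", "sub_cluster": "5.1"},
            "C": {"clade": "II", "sub_cluster": "5.1"},
            "D": {"clade": "II", "sub_cluster": "5.1"},
        }
    )
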