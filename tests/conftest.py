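import numpy as np
import pandas as pd
import pytest

from emts2pca import SampleMetadata, SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small strong-signal series used by several integration tests:
    500 genes, 20 planted, 10+10 learning, 6+6 testing."""
    cfg = SimulationConfig(
        n_genes=500,
        n_signature=20,
        n_confounder_genes=10,
        n_learning_per_group=10,
        n_testing_per_group=6,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture()
def toy_metadata():
    """6+6 learning samples with etiologies, plus 2+2 testing."""
    ids = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)] + ["ta0", "ta1", "tb0", "tb1"]
    group = ["A"] * 6 + ["B"] * 6 + ["A", "A", "B", "B"]
    split = ["learning"] * 12 + ["testing"] * 4
    conf = (["sporadic", "radiation"] * 3) * 2 + ["sporadic"] * 4
    table = pd.DataFrame(
        {"group": group, "split": split, "confounder": conf},
        index=pd.Index(ids, name="sample_id"),
    )
    return SampleMetadata(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
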