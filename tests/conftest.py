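import numpy as np
import pandas as pd
import pytest

from coexprofiler import ModuleSpec, SimulationConfig, generate, load_geneset


@pytest.fixture(scope="session")
def geneset():
    return load_geneset()


@pytest.fixture()
def two_module_setting():
    """A normal-only setting with two planted 4-gene modules (rho=0.9, n=12)."""
    config = SimulationConfig(
        n_genes=16,
        n_control=12,
        modules=(
            ModuleSpec(genes=("g00", "g01", "g02", "g03"), rho=0.9),
            ModuleSpec(genes=("g04", "g05", "g06", "g07"), rho=0.9, signs=(1, -1, 1, -1)),
        ),
        seed=42,
    )
    return generate(config)


def write_tsv_matrix(path, frame):
    out = frame.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(20120404)
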