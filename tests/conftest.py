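import numpy as np
import pandas as pd
import pytest

import immunosort as iso


@pytest.fixture(scope="session")
def small_cfg() -> iso.SimulationConfig:
    """Six-type, 200-gene cohort config used by fast unit tests."""
    return iso.SimulationConfig(
        n_celltypes=6, n_genes=200, markers_per_type=8,
        n_patients=4, cells_per_patient=120, seed=101,
    )


@pytest.fixture(scope="session")
def small_signature(small_cfg) -> iso.SignatureMatrix:
    return iso.true_signature(small_cfg)


@pytest.fixture(scope="session")
def panel_cfg() -> iso.SimulationConfig:
    """Full 21-type panel config at the default study conditions."""
    return iso.SimulationConfig(seed=202)


@pytest.fixture(scope="session")
def panel_signature(panel_cfg) -> iso.SignatureMatrix:
    return iso.true_signature(panel_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_composition(weights: np.ndarray, samples=None, types=None) -> iso.CompositionTable:
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    samples = samples or [f"s{i}" for i in range(weights.shape[0])]
    types = types or [f"ct{i}" for i in range(weights.shape[1])]
    return iso.CompositionTable(data=pd.DataFrame(weights, index=samples, columns=types))
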