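import numpy as np
import pandas as pd
import pytest

from omiconcord import ProcessSpec, SimulationConfig, generate_experiment
from omiconcord.matrix import AnalyteMatrix


@pytest.fixture(scope="session")
def desk_config():
    """Small two-cell-line experiment: 2 primary + 2 secondary processes."""
    return SimulationConfig(
        n_analytes_per_layer={"protein": 140, "phospho": 40, "metabolite": 40, "lipid": 30},
        processes=[
            ProcessSpec("apoptosis", 15, "primary"),
            ProcessSpec("fa_metabolism", 15, "primary"),
            ProcessSpec("glycolysis", 15, "secondary"),
            ProcessSpec("oxphos", 15, "secondary"),
        ],
        n_replicates=3,
        noise_cv=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def desk_experiment(desk_config):
    return generate_experiment(desk_config)


@pytest.fixture
def tiny_matrix():
    """2 analytes x (vehicle + drug) x 3 replicates in one stratum."""
    values = pd.DataFrame(
        {
            "v1": [100.0, 10.0],
            "v2": [110.0, 11.0],
            "v3": [90.0, 9.0],
            "d1": [50.0, 20.0],
            "d2": [55.0, 22.0],
            "d3": [45.0, 18.0],
        },
        index=["a1", "a2"],
    )
    samples = pd.DataFrame(
        {
            "cell_line": ["L"] * 6,
            "treatment": ["vehicle"] * 3 + ["drug"] * 3,
            "timepoint_h": [24] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=values.columns,
    )
    return AnalyteMatrix(values, samples)


def null_experiment(n_analytes, seed, noise_cv=0.2, n_replicates=3):
    """Single-layer experiment with no planted effects."""
    config = SimulationConfig(
        n_analytes_per_layer={"protein": n_analytes},
        processes=[],
        noise_cv=noise_cv,
        n_replicates=n_replicates,
        seed=seed,
    )
    return generate_experiment(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
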