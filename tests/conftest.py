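import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from photolag import (
    AbundanceMatrix,
    NoiseModel,
    PulseDesign,
    generate_dataset,
    sample_table,
)


@pytest.fixture(scope="session")
def design() -> PulseDesign:
    return PulseDesign()


@pytest.fixture(scope="session")
def small_dataset(design):
    """Small noisy two-layer dataset shared across tests (seed 7)."""
    return generate_dataset(
        {"concordant": 40, "transcript_only": 40, "protein_only": 20, "null": 300},
        design=design,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(design):
    """Noise-free twin of a small dataset: exact trajectory values."""
    return generate_dataset(
        {"concordant": 10, "transcript_only": 10, "protein_only": 5, "null": 20},
        design=design,
        noise=NoiseModel.noiseless(),
        seed=7,
    )


def toy_matrix(values: np.ndarray, layer: str, design: PulseDesign | None = None,
               feature_ids=None) -> AbundanceMatrix:
    """Wrap a raw array into an AbundanceMatrix following the default design."""
    design = design or PulseDesign()
    samples = sample_table(design, layer)
    ids = feature_ids or [f"f{i}" for i in range(len(values))]
    return AbundanceMatrix(
        values=pd.DataFrame(values, index=pd.Index(ids, name="feature_id"),
                            columns=samples.index),
        samples=samples,
        layer=layer,
    )
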