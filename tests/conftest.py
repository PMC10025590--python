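import numpy as np
import pytest

from drsim.io import SampleAnnotation, SignatureMatrix
from drsim.metric_learning import TrainingConfig, train
from drsim.synthetic import SimulationConfig, simulate_reference_collection


@pytest.fixture(scope="session")
def small_collection():
    """A compact well-separated synthetic collection (one condition)."""
    config = SimulationConfig(
        n_genes=120,
        n_compounds=6,
        replicates_per_compound=8,
        latent_dim=4,
        class_effect_size=5.0,
        noise_sd=1.0,
        seed=7,
    )
    return simulate_reference_collection(config)


@pytest.fixture(scope="session")
def small_model(small_collection):
    matrix, annotations, _ = small_collection
    return train(matrix, annotations, TrainingConfig())


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(3)
    return SignatureMatrix(
        [f"G{i}" for i in range(5)],
        ["s1", "s2", "s3"],
        rng.normal(size=(5, 3)),
    )


def make_annotations(sample_ids, compounds, cell_line="MCF7", time_point=24):
    return [
        SampleAnnotation(s, c, cell_line, time_point, "1uM")
        for s, c in zip(sample_ids, compounds)
    ]
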