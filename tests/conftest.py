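import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ddecnn import (
    ArchitectureSpec,
    SyntheticSpec,
    TrainingConfig,
    generate_dataset,
)
from ddecnn.evaluation import _featurize

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: A small architecture used wherever the full default would be overkill.
TINY_SPEC = ArchitectureSpec(
    conv_filters=(8,),
    dense_units=16,
    dropout_rates=(0.0, 0.0),
)


@pytest.fixture
def two_record_fasta(tmp_path):
    path = tmp_path / "two.fasta"
    path.write_text(">a\nAC\n>b\nACD\n")
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """A small separable two-class set shared across training tests."""
    spec = SyntheticSpec(
        n_pos=60, n_neg=80, length_min=50, length_max=150, seed=11
    )
    records, labels = generate_dataset(spec)
    return records, labels


@pytest.fixture(scope="session")
def small_tensors(small_dataset):
    records, labels = small_dataset
    return _featurize(records, "sqrt"), labels


@pytest.fixture(scope="session")
def tiny_trained(small_dataset, small_tensors):
    """A fitted small model reused by prediction/persistence/evaluation tests."""
    from ddecnn.cnn import build_model, train

    records, labels = small_dataset
    x, y = small_tensors
    config = TrainingConfig(epochs=25, seed=3)
    model = build_model(TINY_SPEC, config)
    return train(
        model, x, y,
        train_ids=[r.id for r in records],
        feature_meta={"denominator": "sqrt"},
    )
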