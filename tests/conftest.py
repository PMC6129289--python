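import numpy as np
import pytest

from somcoding import (
    GeneratorConfig,
    TrainConfig,
    feature_matrix,
    generate,
    labels_to_matrix,
)
from somcoding.som import train


def split_dataset(transcripts, train_frac=0.7, seed=7):
    """Deterministic shuffled train/test split of a transcript list."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(transcripts))
    n_tr = int(train_frac * len(transcripts))
    return perm[:n_tr], perm[n_tr:]


@pytest.fixture(scope="session")
def separable_dataset():
    """The default separable synthetic dataset with features and split."""
    transcripts = generate(GeneratorConfig(seed=42))
    X = feature_matrix(transcripts)
    labels = np.array([t.label for t in transcripts])
    tr, te = split_dataset(transcripts)
    return {
        "transcripts": transcripts,
        "X": X,
        "labels": labels,
        "Y": labels_to_matrix(labels),
        "train_idx": tr,
        "test_idx": te,
    }


@pytest.fixture(scope="session")
def default_model(separable_dataset):
    """Model trained with default hyperparameters on the separable set."""
    d = separable_dataset
    return train(d["X"][d["train_idx"]], d["Y"][d["train_idx"]], TrainConfig(seed=1))


@pytest.fixture(scope="session")
def boundary_dataset():
    """Dataset with 15% boundary-profile transcripts in each class."""
    transcripts = generate(GeneratorConfig(seed=5, ambiguity_fraction=0.15))
    X = feature_matrix(transcripts)
    labels = np.array([t.label for t in transcripts])
    tr, te = split_dataset(transcripts, seed=11)
    return {
        "transcripts": transcripts,
        "X": X,
        "labels": labels,
        "Y": labels_to_matrix(labels),
        "train_idx": tr,
        "test_idx": te,
    }


@pytest.fixture(scope="session")
def boundary_model(boundary_dataset):
    d = boundary_dataset
    return train(d["X"][d["train_idx"]], d["Y"][d["train_idx"]], TrainConfig(seed=3))
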