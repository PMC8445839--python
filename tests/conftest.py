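"""Shared fixtures: reference sets, fragment table, trained models.

Training is the expensive step, so one model per architecture is trained
once per session on the standard 2000-molecule fixture dataset and shared
across test modules.  The aux model trains at the package-default 30
epochs (its classification term is 1/49 of the loss, so it converges
slowest); baseline and ae converge within a few epochs on the separable
fixture task and train for 10.
"""

from __future__ import annotations

import numpy as np
import pytest

from npfp import (
    FeaturizedDataset,
    ModelSpec,
    OptimizerConfig,
    build_fragment_table,
    generate_np_like,
    generate_synthetic_like,
    make_folds,
    train_fold,
)

FIXTURE_EPOCHS = {"baseline": 10, "aux": 30, "ae": 10}


@pytest.fixture(scope="session")
def np_set():
    return generate_np_like(200, seed=1)


@pytest.fixture(scope="session")
def syn_set():
    return generate_synthetic_like(200, seed=2)


@pytest.fixture(scope="session")
def fragment_table(np_set, syn_set):
    return build_fragment_table(np_set, syn_set)


@pytest.fixture(scope="session")
def training_records():
    """The 2000-molecule fixture training set (1000 per class)."""
    return generate_np_like(1000, seed=1) + generate_synthetic_like(1000, seed=2)


@pytest.fixture(scope="session")
def featurized(training_records):
    return FeaturizedDataset.from_records(training_records)


@pytest.fixture(scope="session")
def fold_split(training_records):
    return make_folds(training_records, k=5, seed=0)


def _train(featurized, fold_split, arch: str):
    spec = ModelSpec(
        arch=arch, seed=0,
        optimizer=OptimizerConfig(lr_max=1e-3, epochs=FIXTURE_EPOCHS[arch],
                                  batch_size=256))
    return train_fold(featurized, fold_split, 0, spec)


@pytest.fixture(scope="session")
def trained_models(featurized, fold_split):
    """One trained model per architecture (fold 0 of the shared split)."""
    return {arch: _train(featurized, fold_split, arch)
            for arch in ("baseline", "aux", "ae")}


@pytest.fixture(scope="session")
def aux_model(trained_models):
    return trained_models["aux"]


@pytest.fixture(scope="session")
def small_records():
    """A small set for cheap per-test training runs."""
    return generate_np_like(150, seed=7) + generate_synthetic_like(150, seed=8)


@pytest.fixture(scope="session")
def small_featurized(small_records):
    return FeaturizedDataset.from_records(small_records)


@pytest.fixture(scope="session")
def small_split(small_records):
    return make_folds(small_records, k=5, seed=3)
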