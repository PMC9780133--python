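"""Shared fixtures.

``default_world`` builds the package's standard study once per session:
the default synthetic dataset (40 APIs, ~500 sprays, 10% relative noise),
an API-grouped cluster-stratified split, the fitted encoder, and the
PLS+SVR averaging ensemble trained on the training partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from spraydry.datasets import GeneratorConfig, GroundTruth, generate_dataset
from spraydry.encoding import SprayFeatureEncoder
from spraydry.modeling import ModelSpec, make_ensemble, train_final
from spraydry.splitting import cluster_apis, split_by_api

SPLIT_SEED = 0


@dataclass
class World:
    dataset: pd.DataFrame
    truth: GroundTruth
    train: pd.DataFrame
    test: pd.DataFrame
    encoder: SprayFeatureEncoder
    X_train: pd.DataFrame
    X_test: pd.DataFrame
    members: list
    ensemble: object


_WORLD_CACHE: dict[int, World] = {}


def build_world(gen_config: GeneratorConfig | None = None, split_seed: int = SPLIT_SEED) -> World:
    if gen_config is None and split_seed in _WORLD_CACHE:
        return _WORLD_CACHE[split_seed]
    dataset, truth = generate_dataset(gen_config or GeneratorConfig())
    clusters = cluster_apis(dataset, 4, seed=split_seed)
    split = split_by_api(clusters, 0.25, seed=split_seed, dataset=dataset)
    train = dataset.loc[split.train_rows]
    test = dataset.loc[split.test_rows]
    encoder = SprayFeatureEncoder().fit(train)
    X_train = encoder.transform(train)
    X_test = encoder.transform(test)
    members = [
        train_final(ModelSpec(f), X_train, train["d50"], seed=0) for f in ("pls", "svr")
    ]
    ensemble = make_ensemble(members, encoder=encoder.state_)
    world = World(dataset, truth, train, test, encoder, X_train, X_test, members, ensemble)
    if gen_config is None:
        _WORLD_CACHE[split_seed] = world
    return world


@pytest.fixture(scope="session")
def default_world() -> World:
    return build_world()


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast dataset for I/O and CLI tests."""
    frame, truth = generate_dataset(
        GeneratorConfig(n_apis=8, sprays_per_api=(6, 10), n_nozzles=10, seed=11)
    )
    return frame, truth
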