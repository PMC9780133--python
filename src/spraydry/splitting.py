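"""API-grouped data splitting and cross-validation folds.

All sprays of an API live on one side of the train/test split: at predict
time the model has never seen the API, so evaluation must respect the same
boundary or API-specific formulation/size patterns leak into the score.
Test APIs are sampled per cluster of API profiles so train and test cover
similar formulation/process populations, and cross-validation is
leave-one-API-out (one fold per API in the training set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .schema import FORMULATION_NUMERIC, PROCESS_PARAMS, SOLVENT_PREFIX

__all__ = ["SplitResult", "api_profiles", "cluster_apis", "split_by_api", "logo_folds"]


@dataclass
class SplitResult:
    train_apis: set = field(default_factory=set)
    test_apis: set = field(default_factory=set)
    train_rows: list = field(default_factory=list)
    test_rows: list = field(default_factory=list)
    cluster_of: dict = field(default_factory=dict)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Audit table: one row per API with cluster and partition."""
        rows = [
            {
                "api_id": api,
                "cluster": self.cluster_of.get(api, -1),
                "partition": "test" if api in self.test_apis else "train",
            }
            for api in sorted(self.train_apis | self.test_apis)
        ]
        return pd.DataFrame(rows)


def api_profiles(dataset: pd.DataFrame, attributes: list[str] | None = None) -> pd.DataFrame:
    """Aggregate each API to a profile vector: per-API means of numeric
    attributes, min-max scaled across APIs, plus polymer-type indicators.

    ``attributes`` restricts the numeric columns used (default: all
    formulation + process numerics and solvent fractions).
    """
    numeric = attributes or [
        *FORMULATION_NUMERIC,
        *PROCESS_PARAMS,
        *[c for c in dataset.columns if c.startswith(SOLVENT_PREFIX)],
    ]
    prof = dataset.groupby("api_id", sort=True)[numeric].mean()
    lo, hi = prof.min(), prof.max()
    span = (hi - lo).replace(0.0, 1.0)
    prof = (prof - lo) / span
    poly = pd.get_dummies(dataset["polymer_type"], prefix="poly").astype(float)
    poly["api_id"] = dataset["api_id"].to_numpy()
    prof = prof.join(poly.groupby("api_id").mean())
    return prof


def cluster_apis(
    dataset: pd.DataFrame,
    n_clusters: int,
    seed: int = 0,
    attributes: list[str] | None = None,
) -> dict[str, int]:
    """Centroid-cluster API profiles; deterministic under a fixed seed."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    prof = api_profiles(dataset, attributes)
    if len(prof) < n_clusters:
        raise ValueError(f"only {len(prof)} APIs for {n_clusters} clusters")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(prof.to_numpy())
    return {api: int(lab) for api, lab in zip(prof.index, labels)}


def split_by_api(
    clusters: dict[str, int],
    test_fraction: float = 0.25,
    seed: int = 0,
    dataset: pd.DataFrame | None = None,
) -> SplitResult:
    """Sample ``ceil(test_fraction * |cluster|)`` APIs per cluster into the
    test set; every spray follows its API. Row indices are filled when the
    dataset is supplied."""
    if not clusters:
        raise ValueError("clusters is empty")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    result = SplitResult(cluster_of=dict(clusters), seed=seed)
    by_cluster: dict[int, list[str]] = {}
    for api in sorted(clusters):
        by_cluster.setdefault(clusters[api], []).append(api)
    for label in sorted(by_cluster):
        members = by_cluster[label]
        n_test = int(np.ceil(test_fraction * len(members)))
        picked = set(rng.choice(members, size=n_test, replace=False))
        result.test_apis |= picked
        result.train_apis |= set(members) - picked
    if dataset is not None:
        in_test = dataset["api_id"].isin(result.test_apis)
        result.test_rows = list(dataset.index[in_test])
        result.train_rows = list(dataset.index[~in_test])
    return result


def logo_folds(train: pd.DataFrame):
    """Leave-one-API-out folds over a training frame.

    Yields ``(fit_index, holdout_index)`` pairs, one per API in ascending
    api_id order; the holdouts partition the training rows.
    """
    apis = sorted(train["api_id"].unique())
    if len(apis) < 2:
        raise ValueError("leave-one-API-out CV needs at least 2 APIs")
    for api in apis:
        mask = train["api_id"] == api
        yield train.index[~mask], train.index[mask]
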