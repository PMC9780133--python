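"""Shapley additive attribution of model predictions.

Each prediction is decomposed into a base value (the expected model output
over a background sample) plus one additive contribution per feature, using
the Shapley kernel: coalitions of features are sampled, absent features are
replaced by background values (the interventional value function), and a
kernel-weighted linear regression over coalition indicators yields the
contributions. The regression is solved *subject to* the additivity
constraint, so

    base_value + sum(contributions) == prediction

holds exactly (to solver round-off), not just in expectation. For models
with at most 12 features all 2^d coalitions are enumerated and the result is
the exact Shapley value.

Ensemble attributions are the arithmetic mean of member attributions; since
the ensemble prediction is the mean of member predictions, local accuracy is
inherited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "AttributionVector",
    "attribute_instance",
    "attribute_ensemble",
    "global_importance",
    "waterfall_table",
]

#: Exact coalition enumeration is used at or below this feature count.
EXACT_LIMIT = 12

#: Default background subsample size.
BACKGROUND_SIZE = 100


@dataclass
class AttributionVector:
    base_value: float  # expected model output over the background, um
    contributions: pd.Series  # per-feature contribution, um
    prediction: float  # model output at the instance, um

    @property
    def local_accuracy_gap(self) -> float:
        return abs(self.base_value + float(self.contributions.sum()) - self.prediction)


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _predict_fn(model):
    return model if callable(model) and not hasattr(model, "predict") else model.predict


def _coalitions(d: int, n_coalitions: int | None, rng: np.random.Generator):
    """Coalition indicator matrix Z (excluding empty/full) and LS weights."""
    if d <= EXACT_LIMIT:
        rows, weights = [], []
        for s in range(1, d):
            w = (d - 1) / (s * (d - s))  # Shapley kernel, size-s subsets share it
            for subset in combinations(range(d), s):
                z = np.zeros(d)
                z[list(subset)] = 1.0
                rows.append(z)
                weights.append(w)
        return np.array(rows), np.array(weights)
    n = int(n_coalitions)
    sizes = np.arange(1, d)
    p = (d - 1) / (sizes * (d - sizes))
    p /= p.sum()
    rows = []
    # paired sampling: each coalition enters with its complement
    for _ in range(n // 2):
        s = int(rng.choice(sizes, p=p))
        subset = rng.choice(d, size=s, replace=False)
        z = np.zeros(d)
        z[subset] = 1.0
        rows.append(z)
        rows.append(1.0 - z)
    if n % 2:
        s = int(rng.choice(sizes, p=p))
        z = np.zeros(d)
        z[rng.choice(d, size=s, replace=False)] = 1.0
        rows.append(z)
    Z = np.array(rows)
    return Z, np.ones(len(Z))  # sampling already follows the kernel


def attribute_instance(
    model,
    instance,
    background,
    n_coalitions: int | None = None,
    seed: int = 0,
) -> AttributionVector:
    """Shapley attribution of one prediction against a background sample.

    ``model`` is an object with ``predict`` or a plain callable; ``instance``
    a single feature row; ``background`` the reference rows defining "feature
    absent" (subsampled to 100 rows when larger). ``n_coalitions`` defaults
    to ``max(4 * d, 2 * d + 16)`` and must be at least ``2 * d``.
    """
    predict = _predict_fn(model)
    bg, names = _as_matrix(background)
    if isinstance(instance, pd.Series):
        x = instance.to_numpy(dtype=float)
        names = list(instance.index)
    else:
        x = np.asarray(instance, dtype=float).ravel()
    d = x.size
    if bg.shape[0] == 0:
        raise ValueError("background must be non-empty")
    rng = np.random.default_rng(seed)
    if bg.shape[0] > BACKGROUND_SIZE:
        bg = bg[rng.choice(bg.shape[0], size=BACKGROUND_SIZE, replace=False)]
    if n_coalitions is None:
        n_coalitions = max(4 * d, 2 * d + 16)
    elif d > EXACT_LIMIT and n_coalitions < 2 * d:
        raise ValueError(f"n_coalitions must be >= 2 * n_features ({2 * d})")

    fx = float(np.asarray(predict(x.reshape(1, -1))).ravel()[0])
    base = float(np.mean(np.asarray(predict(bg)).ravel()))

    if np.allclose(bg, x[None, :]):
        warnings.warn("background identical to instance; contributions are zero", UserWarning)
        return AttributionVector(base, pd.Series(np.zeros(d), index=names), fx)

    Z, w = _coalitions(d, n_coalitions, rng)
    m, B = Z.shape[0], bg.shape[0]
    # synthetic rows: background with present features overwritten by x
    synth = np.repeat(bg[None, :, :], m, axis=0)  # (m, B, d)
    synth = np.where(Z[:, None, :] == 1.0, x[None, None, :], synth)
    v = np.asarray(predict(synth.reshape(m * B, d))).reshape(m, B).mean(axis=1)

    # weighted LS with the additivity constraint eliminated into the last phi
    y = v - base
    total = fx - base
    Zr = Z[:, :-1] - Z[:, -1:]
    yr = y - Z[:, -1] * total
    sw = np.sqrt(w)
    phi_r, *_ = np.linalg.lstsq(Zr * sw[:, None], yr * sw, rcond=None)
    phi = np.append(phi_r, total - phi_r.sum())
    return AttributionVector(base, pd.Series(phi, index=names), fx)


def attribute_ensemble(
    ensemble, instance, background, n_coalitions: int | None = None, seed: int = 0
) -> AttributionVector:
    """Mean of member attributions (members share the feature space)."""
    members = getattr(ensemble, "members_", None)
    if not members:
        raise ValueError("ensemble has no fitted members")
    parts = [
        attribute_instance(m, instance, background, n_coalitions=n_coalitions, seed=seed)
        for m in members
    ]
    contributions = pd.concat([p.contributions for p in parts], axis=1).mean(axis=1)
    base = float(np.mean([p.base_value for p in parts]))
    prediction = float(np.mean([p.prediction for p in parts]))
    return AttributionVector(base, contributions, prediction)


def global_importance(
    attributions: list[AttributionVector], instances: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Rank features by mean absolute contribution.

    ``sign_trend`` is the Spearman correlation between feature value and
    contribution across instances (the direction a beeswarm plot shows);
    NaN when instances are not supplied or a feature is constant.
    """
    if not attributions:
        raise ValueError("need at least one attribution")
    contrib = pd.DataFrame([a.contributions for a in attributions]).reset_index(drop=True)
    mean_abs = contrib.abs().mean(axis=0)
    trends = {}
    for feature in contrib.columns:
        trend = float("nan")
        if instances is not None and feature in instances.columns:
            values = instances[feature].to_numpy(dtype=float)
            if np.ptp(values) > 0 and np.ptp(contrib[feature].to_numpy()) > 0:
                trend = float(spearmanr(values, contrib[feature]).statistic)
        trends[feature] = trend
    table = pd.DataFrame(
        {"mean_abs_contribution": mean_abs, "sign_trend": pd.Series(trends)}
    )
    table.index.name = "feature"
    return table.sort_values("mean_abs_contribution", ascending=False)


def waterfall_table(attribution: AttributionVector) -> pd.DataFrame:
    """Per-instance decomposition ordered by decreasing |contribution|;
    the final running total equals the prediction."""
    order = attribution.contributions.abs().sort_values(ascending=False).index
    running = attribution.base_value
    rows = []
    for feature in order:
        c = float(attribution.contributions[feature])
        running += c
        rows.append({"feature": feature, "contribution": c, "running_total": running})
    return pd.DataFrame(rows)
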