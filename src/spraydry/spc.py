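"""Multivariate statistical process control via PCA.

A PCA model fitted on (standardized) historical training data defines the
correlation structure of feasible operating points. Two statistics locate a
candidate point relative to that structure:

- Hotelling's T2: the Mahalanobis distance of the candidate's scores within
  the retained subspace, ``T2 = sum_i t_i^2 / lambda_i``. Large T2 = the
  candidate is an outlier along directions the data does vary in.
- Q (squared prediction error): the squared residual norm off the retained
  subspace. Large Q = the candidate breaks the correlation structure.

Upper control limits at confidence ``alpha`` (default 99.73%, the 3-sigma
convention):

    T2_UCL = a (n - 1)(n + 1) / (n (n - a)) * F^-1(alpha; a, n - a)

(the new-observation form) and Q_UCL by the Jackson-Mudholkar closed form
from the moments of the discarded eigenvalues.

The retained component count is the rounded average of several selection
strategies (eigenvalue-greater-than-mean, Horn's parallel analysis, and a
permutation test), a pluggable set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SPCModel", "fit_spc", "t2_q", "suggest_n_components", "COMPONENT_STRATEGIES"]


def _sorted_eigenvalues(X_std: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvalsh(np.cov(X_std, rowvar=False, ddof=1))
    return np.clip(lam[::-1], 0.0, None)


def _eigenvalue_mean(X_std, rng) -> int:
    lam = _sorted_eigenvalues(X_std)
    return int(np.sum(lam > lam.mean()))


def _parallel_analysis(X_std, rng, n_draws: int = 20) -> int:
    """Horn's parallel analysis: retain components whose eigenvalue exceeds
    the mean eigenvalue of same-shape uncorrelated Gaussian data."""
    n, d = X_std.shape
    lam = _sorted_eigenvalues(X_std)
    ref = np.zeros(d)
    for _ in range(n_draws):
        sim = rng.standard_normal((n, d))
        sim = (sim - sim.mean(0)) / sim.std(0, ddof=1)
        ref += _sorted_eigenvalues(sim)
    ref /= n_draws
    above = lam > ref
    return int(above.argmin()) if not above.all() else int(above.size)


def _permutation_test(X_std, rng, n_draws: int = 20, q: float = 0.95) -> int:
    """Retain the leading run of eigenvalues exceeding the q-quantile of
    eigenvalues from column-permuted (decorrelated) data."""
    n, d = X_std.shape
    lam = _sorted_eigenvalues(X_std)
    sims = np.empty((n_draws, d))
    for k in range(n_draws):
        perm = np.column_stack([rng.permutation(X_std[:, j]) for j in range(d)])
        sims[k] = _sorted_eigenvalues(perm)
    thresh = np.quantile(sims, q, axis=0)
    above = lam > thresh
    return int(above.argmin()) if not above.all() else int(above.size)


COMPONENT_STRATEGIES = {
    "eigenvalue_mean": _eigenvalue_mean,
    "parallel_analysis": _parallel_analysis,
    "permutation": _permutation_test,
}


def suggest_n_components(X_std: np.ndarray, seed: int = 0, strategies=None) -> int:
    """Rounded average of the component counts suggested by each strategy,
    never below 1."""
    strategies = strategies or COMPONENT_STRATEGIES
    counts = [
        fn(X_std, np.random.default_rng(seed + i))
        for i, fn in enumerate(strategies.values())
    ]
    return max(1, int(round(float(np.mean(counts)))))


@dataclass
class SPCModel:
    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (d, a) orthonormal columns
    eigenvalues: np.ndarray  # retained, descending
    residual_eigenvalues: np.ndarray
    t2_ucl: float
    q_ucl: float
    alpha: float
    n_samples: int
    component_counts: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _q_ucl(residual_eigenvalues: np.ndarray, alpha: float) -> float:
    """Jackson-Mudholkar closed form from residual-eigenvalue moments."""
    lam = residual_eigenvalues[residual_eigenvalues > 1e-12]
    if lam.size == 0:
        warnings.warn("no residual variance: Q control limit is +inf", UserWarning)
        return float("inf")
    th1, th2, th3 = lam.sum(), (lam**2).sum(), (lam**3).sum()
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    c = stats.norm.ppf(alpha)
    inner = c * np.sqrt(2.0 * th2 * h0**2) / th1 + 1.0 + th2 * h0 * (h0 - 1.0) / th1**2
    if inner <= 0:  # extreme eigenvalue spectra: fall back to weighted chi2 bound
        return float(th1 * stats.chi2.ppf(alpha, df=1))
    return float(th1 * inner ** (1.0 / h0))


def fit_spc(
    train,
    alpha: float = 0.9973,
    n_components: int | None = None,
    seed: int = 0,
    strategies=None,
) -> SPCModel:
    """Fit a per-scale SPC model on (unstandardized) training features.

    Features are standardized internally; constant columns get unit scale.
    ``n_components`` overrides the strategy-average selection.
    """
    if isinstance(train, pd.DataFrame):
        names = list(train.columns)
        X = train.to_numpy(dtype=float)
    else:
        X = np.asarray(train, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    n, d = X.shape
    if n < 10:
        raise ValueError(f"SPC model needs at least 10 rows, got {n}")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    X_std = (X - mean) / scale

    counts = {}
    if n_components is None:
        strategies = strategies or COMPONENT_STRATEGIES
        counts = {
            name: fn(X_std, np.random.default_rng(seed + i))
            for i, (name, fn) in enumerate(strategies.items())
        }
        a = max(1, int(round(float(np.mean(list(counts.values()))))))
    else:
        a = int(n_components)
    if a >= min(n - 1, d):
        raise ValueError(
            f"retained components a={a} must be < min(rows - 1, features) "
            f"= {min(n - 1, d)}"
        )

    cov = np.cov(X_std, rowvar=False, ddof=1)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = np.clip(lam[order], 0.0, None), vec[:, order]

    t2_ucl = (
        a * (n - 1) * (n + 1) / (n * (n - a)) * stats.f.ppf(alpha, a, n - a)
    )
    q_ucl = _q_ucl(lam[a:], alpha)
    return SPCModel(
        feature_names=names,
        mean=mean,
        scale=scale,
        loadings=vec[:, :a],
        eigenvalues=lam[:a],
        residual_eigenvalues=lam[a:],
        t2_ucl=float(t2_ucl),
        q_ucl=q_ucl,
        alpha=alpha,
        n_samples=n,
        component_counts=counts,
    )


def t2_q(x, spc: SPCModel) -> tuple[float, float]:
    """T2 and Q of one candidate row (raw feature space).

    Vectorized: a 2-D input returns arrays.
    """
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if not np.isfinite(arr).all():
        raise ValueError("t2_q requires finite input")
    z = (arr - spc.mean) / spc.scale
    scores = z @ spc.loadings
    lam = np.where(spc.eigenvalues > 1e-12, spc.eigenvalues, np.inf)
    t2 = (scores**2 / lam).sum(axis=1)
    resid = z - scores @ spc.loadings.T
    q = (resid**2).sum(axis=1)
    if single:
        return float(t2[0]), float(q[0])
    return t2, q
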