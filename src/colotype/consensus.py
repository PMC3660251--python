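"""Consensus hierarchical clustering of tumor expression profiles.

Robust subtype discovery: the base clusterer (Ward linkage on
1 − Pearson-correlation distance between samples) is re-run over many random
subsamples of samples and features, and the fraction of runs in which two
samples co-cluster — among runs where both were drawn — forms the consensus
matrix.  The number of clusters is chosen from the distribution of
consensus values: by default the largest k whose consensus matrix is still
(nearly) unambiguous (PAC criterion), with the area under the
consensus-value CDF and its relative increases (delta-area criterion)
computed alongside as diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

DELTA_AREA_THRESHOLD = 0.025


@dataclass
class ConsensusConfig:
    """Resampling settings; defaults: 1,000 iterations, 90% of samples and
    90% of features drawn without replacement each iteration."""

    k_range: tuple[int, int] = (2, 10)
    n_iter: int = 1000
    sample_frac: float = 0.9
    feature_frac: float = 0.9
    linkage: str = "ward"
    distance: str = "one_minus_pearson"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.sample_frac <= 1 and 0 < self.feature_frac <= 1):
            raise ValueError("sample_frac and feature_frac must be in (0, 1]")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("k_range must be an inclusive range with min >= 2")
        if self.linkage != "ward" or self.distance != "one_minus_pearson":
            raise ValueError("only ward linkage on 1-Pearson is supported")


@dataclass
class ConsensusRun:
    """Consensus matrix, co-sampling counts and final labels for one k."""

    k: int
    M: pd.DataFrame
    co_sampled: pd.DataFrame
    labels: pd.Series


@dataclass
class KSelection:
    """Area under the consensus CDF per k, relative increases, the
    proportion of ambiguous consensus values per k, and the selected k."""

    areas: dict[int, float]
    deltas: dict[int, float]
    pac: dict[int, float]
    k_selected: int


def pearson_distance(X: np.ndarray) -> np.ndarray:
    """Square matrix of 1 − Pearson correlation between rows of ``X``."""
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _check_sample_variance(X: np.ndarray, sample_ids) -> None:
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [str(sample_ids[i]) for i in bad[:5]]
        raise ValueError(
            "zero-variance sample(s), Pearson distance undefined: "
            + ", ".join(names))


def cluster_ward_pearson(expr: pd.DataFrame, k: int) -> pd.Series:
    """Cut the Ward tree on 1 − Pearson distance between samples into ``k``
    groups.  ``expr`` is genes x samples; labels are integers 1..k."""
    n = expr.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    X = expr.to_numpy().T
    _check_sample_variance(X, expr.columns)
    d = pearson_distance(X)
    Z = linkage(squareform(d, checks=False), method="ward")
    labels = fcluster(Z, k, criterion="maxclust")
    return pd.Series(labels, index=expr.columns, name="cluster")


def _consensus_counts(X: np.ndarray, ks: Iterable[int], n_iter: int,
                      sample_frac: float, feature_frac: float,
                      rng: np.random.Generator):
    """Accumulate co-clustering and co-sampling counts.

    One subsample and one linkage per iteration, cut at every requested k —
    the per-pair co-sampling counts are identical across k.
    """
    n, p = X.shape
    m = int(np.ceil(sample_frac * n))
    q = int(np.ceil(feature_frac * p))
    ks = sorted(set(ks))
    co_clustered = {k: np.zeros((n, n)) for k in ks}
    co_sampled = np.zeros((n, n))
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        feats = rng.choice(p, size=q, replace=False)
        sub = X[np.ix_(idx, feats)]
        d = pearson_distance(sub)
        Z = linkage(squareform(d, checks=False), method="ward")
        co_sampled[np.ix_(idx, idx)] += 1
        for k in ks:
            labs = fcluster(Z, min(k, m), criterion="maxclust")
            for c in np.unique(labs):
                members = idx[labs == c]
                co_clustered[k][np.ix_(members, members)] += 1
    return co_clustered, co_sampled


def _finalize_run(k: int, co_clustered: np.ndarray, co_sampled: np.ndarray,
                  sample_ids) -> ConsensusRun:
    n = co_sampled.shape[0]
    never = (co_sampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning("%d sample pairs never co-sampled; consensus set to 0",
                       int(never.sum()) // 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(co_sampled > 0, co_clustered / np.maximum(co_sampled, 1),
                     0.0)
    np.fill_diagonal(M, 1.0)
    M = (M + M.T) / 2.0  # numerically symmetric
    Z = linkage(squareform(1.0 - M, checks=False), method="average")
    labels = fcluster(Z, k, criterion="maxclust")
    ids = list(sample_ids)
    return ConsensusRun(
        k=k,
        M=pd.DataFrame(M, index=ids, columns=ids),
        co_sampled=pd.DataFrame(co_sampled.astype(int), index=ids,
                                columns=ids),
        labels=pd.Series(labels, index=ids, name="subtype"),
    )


class ConsensusClustering(BaseEstimator, ClusterMixin):
    """Consensus Ward/Pearson clustering as a scikit-learn style clusterer.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k.
    n_iter : int
        Resampling iterations (default 1000).
    sample_frac, feature_frac : float
        Fractions of samples and features drawn (without replacement) per
        iteration (default 0.9 each).
    random_state : int
        Seed for the resampling streams.

    Attributes
    ----------
    consensus_matrix_ : ndarray, (n_samples, n_samples)
        Co-clustering rate among co-sampled runs; diagonal 1.
    co_sampled_ : ndarray of int
        Number of iterations each pair was jointly drawn.
    labels_ : ndarray
        Final assignment from average-linkage clustering of
        1 − consensus, cut at ``n_clusters``.
    """

    def __init__(self, n_clusters: int = 6, n_iter: int = 1000,
                 sample_frac: float = 0.9, feature_frac: float = 0.9,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_iter = n_iter
        self.sample_frac = sample_frac
        self.feature_frac = feature_frac
        self.random_state = random_state

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        cfg = ConsensusConfig(
            k_range=(2, max(2, self.n_clusters)), n_iter=self.n_iter,
            sample_frac=self.sample_frac, feature_frac=self.feature_frac,
            seed=self.random_state)
        cfg.validate()
        arr = X.to_numpy(dtype=float)
        _check_sample_variance(arr, list(X.index))
        rng = np.random.default_rng(self.random_state)
        co_c, co_s = _consensus_counts(
            arr, [self.n_clusters], self.n_iter, self.sample_frac,
            self.feature_frac, rng)
        run = _finalize_run(self.n_clusters, co_c[self.n_clusters], co_s,
                            list(X.index))
        self.consensus_matrix_ = run.M.to_numpy()
        self.co_sampled_ = run.co_sampled.to_numpy()
        self.labels_ = run.labels.to_numpy()
        self.run_ = run
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def run_consensus(expr: pd.DataFrame, k: int, config: ConsensusConfig
                  ) -> ConsensusRun:
    """Consensus clustering of a genes x samples matrix at one k."""
    config.validate()
    est = ConsensusClustering(
        n_clusters=k, n_iter=config.n_iter, sample_frac=config.sample_frac,
        feature_frac=config.feature_frac, random_state=config.seed)
    est.fit(expr.T)
    return est.run_

def run_consensus_scan(expr: pd.DataFrame, config: ConsensusConfig
                       ) -> dict[int, ConsensusRun]:
    """Consensus runs for every k in ``config.k_range``.

    All k share the same per-iteration subsamples and linkage (the tree is
    cut at each k), so a scan costs the same as a single-k run.
    """
    config.validate()
    ks = list(range(config.k_range[0], config.k_range[1] + 1))
    arr = expr.to_numpy(dtype=float).T
    _check_sample_variance(arr, list(expr.columns))
    rng = np.random.default_rng(config.seed)
    co_c, co_s = _consensus_counts(arr, ks, config.n_iter, config.sample_frac,
                                   config.feature_frac, rng)
    return {k: _finalize_run(k, co_c[k], co_s, list(expr.columns))
            for k in ks}


def consensus_cdf_area(M: pd.DataFrame | np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle consensus values,
    integrated over [0, 1]."""
    A = np.asarray(M, dtype=float)
    v = A[np.triu_indices(A.shape[0], k=1)]
    if v.size == 0:
        raise ValueError("consensus matrix has no off-diagonal entries")
    # empirical CDF is a step function jumping at each distinct value;
    # integrate it piecewise over [0, 1]
    u, counts = np.unique(v, return_counts=True)
    F = np.cumsum(counts) / v.size
    xs = np.concatenate((u, [1.0]))
    return float(np.sum(F * np.diff(xs)))


PAC_BOUNDS = (0.1, 0.9)
PAC_TOLERANCE = 0.01


def proportion_ambiguous(M: pd.DataFrame | np.ndarray,
                         bounds: tuple[float, float] = PAC_BOUNDS) -> float:
    """PAC: fraction of off-diagonal consensus values falling strictly
    between the bounds, i.e. pairs that neither always nor never
    co-cluster.  Near zero when the clustering is stable."""
    A = np.asarray(M, dtype=float)
    v = A[np.triu_indices(A.shape[0], k=1)]
    lo, hi = bounds
    return float(((v > lo) & (v < hi)).mean())


def select_k(runs: Mapping[int, ConsensusRun],
             threshold: float = DELTA_AREA_THRESHOLD,
             method: str = "pac",
             pac_bounds: tuple[float, float] = PAC_BOUNDS,
             pac_tol: float = PAC_TOLERANCE) -> KSelection:
    """Choose the number of clusters from a scan of consensus runs.

    Both diagnostics of the consensus-value distribution are computed for
    every k: the area under its CDF (with the relative delta-area curve)
    and the proportion of ambiguous consensus values (PAC).

    ``method='pac'`` (default) selects the largest k whose PAC is within
    ``pac_tol`` of the minimum over the scan — the most granular clustering
    that is still (nearly) perfectly stable.  ``method='delta_area'``
    selects the largest k whose relative area increase reaches
    ``threshold``.
    """
    if not runs:
        raise ValueError("no consensus runs supplied")
    ks = sorted(runs)
    areas = {k: consensus_cdf_area(runs[k].M) for k in ks}
    pac = {k: proportion_ambiguous(runs[k].M, pac_bounds) for k in ks}
    deltas: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            if prev > 0:
                deltas[k] = (areas[k] - prev) / prev
            else:
                deltas[k] = 0.0 if areas[k] == 0 else np.inf
    if method == "delta_area":
        admissible = [k for k in ks if deltas[k] >= threshold]
    elif method == "pac":
        best = min(pac.values())
        admissible = [k for k in ks if pac[k] <= best + pac_tol]
    else:
        raise ValueError(f"unknown selection method {method!r}")
    k_selected = max(admissible) if admissible else ks[0]
    return KSelection(areas=areas, deltas=deltas, pac=pac,
                      k_selected=k_selected)
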