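"""Consensus clustering of samples on regulator (or DEG) expression.

Resampled k-means consensus clustering: for each of ``n_reps`` replicates a
fraction of samples is drawn without replacement, k-means (Euclidean) is run
on the subsample, and co-clustering is accumulated into an n x n consensus
matrix M_k = co-cluster count / co-sample count. Final labels come from an
average-linkage hierarchical cut of 1 - M_k. The number of clusters is
selected by PAC (proportion of ambiguous clustering), the standard
quantitative proxy for consensus-CDF stability; the delta-area of the
consensus CDF is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .dataio import ClinicalTable, ExpressionMatrix
from .survstat import km_median_or_rmst
from .syndata import DEFAULT_REGULATORS


@dataclass(frozen=True)
class RegulatorPanel:
    """The 16-gene m6A regulator panel: 8 writers, 7 readers, 1 eraser."""

    writers: tuple = DEFAULT_REGULATORS[:8]
    readers: tuple = DEFAULT_REGULATORS[8:15]
    erasers: tuple = DEFAULT_REGULATORS[15:]

    def __post_init__(self) -> None:
        if len(set(self.all_genes)) != len(self.all_genes):
            raise ValueError("regulator panel contains duplicate symbols")

    @property
    def all_genes(self) -> tuple:
        return self.writers + self.readers + self.erasers


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, stability summaries and final labels."""

    samples: pd.Index
    consensus: dict               # k -> (n, n) ndarray
    labels: dict                  # k -> ndarray of labels in {1..k}
    pac: dict                     # k -> float
    cdf_area: dict                # k -> area under the consensus CDF
    delta_area: dict              # k -> relative CDF-area increase
    chosen_k: int = None

    def labels_series(self, k=None) -> pd.Series:
        k = self.chosen_k if k is None else k
        return pd.Series(self.labels[k], index=self.samples, name="cluster")


class ConsensusKMeans(BaseEstimator):
    """Resampled k-means consensus clusterer over a range of k.

    Parameters
    ----------
    k_max : int
        Largest number of clusters evaluated (k runs 2..k_max).
    n_reps : int
        Resampling replicates per k (study-scale default 1000).
    subsample : float
        Fraction of samples drawn without replacement per replicate.
        Features are never subsampled.
    n_init : int
        Random k-means restarts per replicate (best inertia kept).
    pac_band : tuple
        Open interval of "ambiguous" consensus values for PAC.
    random_state : int
        Seed; the run is bit-reproducible for a fixed seed.

    Attributes
    ----------
    result_ : ConsensusResult
    best_k_ : int
        argmin PAC, ties broken toward smaller k.
    labels_ : ndarray
        Final labels at ``best_k_``.
    """

    def __init__(self, k_max=10, n_reps=1000, subsample=0.8, n_init=20,
                 pac_band=(0.1, 0.9), random_state=0):
        self.k_max = k_max
        self.n_reps = n_reps
        self.subsample = subsample
        self.n_init = n_init
        self.pac_band = pac_band
        self.random_state = random_state

    def fit(self, X, y=None, sample_index=None):
        """Cluster rows of ``X`` (samples x features)."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0 < self.subsample <= 1):
            raise ValueError("subsample must be in (0, 1]")
        if n <= self.k_max:
            raise ValueError(f"need more samples ({n}) than clusters ({self.k_max})")
        if sample_index is None:
            sample_index = pd.RangeIndex(n)

        sub_n = max(2, int(round(self.subsample * n)))
        ks = range(2, self.k_max + 1)
        consensus, labels, pac, cdf_area = {}, {}, {}, {}
        root = np.random.SeedSequence(self.random_state)
        for k, ss in zip(ks, root.spawn(len(list(ks)))):
            rng = np.random.default_rng(ss)
            co_cluster = np.zeros((n, n))
            co_sample = np.zeros((n, n))
            for _ in range(self.n_reps):
                if sub_n < n:
                    idx = np.sort(rng.choice(n, size=sub_n, replace=False))
                else:
                    idx = np.arange(n)
                km_seed = int(rng.integers(0, 2**31 - 1))
                km = KMeans(n_clusters=k, n_init=self.n_init, random_state=km_seed)
                assign = km.fit_predict(X[idx])
                Z = np.zeros((len(idx), k))
                Z[np.arange(len(idx)), assign] = 1.0
                block = np.ix_(idx, idx)
                co_cluster[block] += Z @ Z.T
                co_sample[block] += 1.0
            with np.errstate(invalid="ignore", divide="ignore"):
                M = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
            np.fill_diagonal(M, 1.0)
            M = (M + M.T) / 2.0
            consensus[k] = M
            labels[k] = self._cut(M, k)
            pac[k] = self._pac(M)
            cdf_area[k] = self._cdf_area(M)

        delta_area = {}
        prev = None
        for k in sorted(cdf_area):
            a = cdf_area[k]
            delta_area[k] = a if prev is None else (a - prev) / prev
            prev = a

        best_k = min(sorted(pac), key=lambda k: (pac[k], k))
        self.result_ = ConsensusResult(
            samples=pd.Index(sample_index), consensus=consensus, labels=labels,
            pac=pac, cdf_area=cdf_area, delta_area=delta_area, chosen_k=best_k,
        )
        self.best_k_ = best_k
        self.labels_ = labels[best_k]
        return self

    def fit_predict(self, X, y=None, sample_index=None):
        return self.fit(X, y, sample_index=sample_index).labels_

    @staticmethod
    def _cut(M, k):
        dist = squareform(1.0 - M, checks=False)
        tree = linkage(dist, method="average")
        return fcluster(tree, t=k, criterion="maxclust")

    def _pac(self, M):
        lo, hi = self.pac_band
        tri = M[np.triu_indices_from(M, k=1)]
        return float(np.mean((tri > lo) & (tri < hi)))

    @staticmethod
    def _cdf_area(M, grid_points=101):
        tri = M[np.triu_indices_from(M, k=1)]
        grid = np.linspace(0, 1, grid_points)
        cdf = np.searchsorted(np.sort(tri), grid, side="right") / tri.size
        return float(np.trapezoid(cdf, grid))


def consensus_cluster(expr_subset: ExpressionMatrix, kmax: int = 10,
                      reps: int = 1000, subsample: float = 0.8,
                      seed: int = 0, n_init: int = 20,
                      standardize: bool = True) -> ConsensusResult:
    """Consensus-cluster the samples of a feature-restricted matrix.

    Rows of ``expr_subset`` are the clustering features (e.g. the 16
    regulators); they are z-scored per gene before Euclidean k-means unless
    ``standardize=False``.
    """
    X = expr_subset.data.to_numpy(dtype=float).T  # samples x features
    if standardize:
        sd = X.std(axis=0, ddof=0)
        if (sd == 0).any():
            zero = expr_subset.genes[sd == 0].tolist()
            raise ValueError(f"zero-variance clustering features: {zero}")
        X = (X - X.mean(axis=0)) / sd
    est = ConsensusKMeans(k_max=kmax, n_reps=reps, subsample=subsample,
                          n_init=n_init, random_state=seed)
    est.fit(X, sample_index=expr_subset.samples)
    return est.result_


def select_k(result: ConsensusResult) -> int:
    """Smallest k minimizing PAC (ties toward smaller k)."""
    return min(sorted(result.pac), key=lambda k: (result.pac[k], k))


def label_m6a_clusters(labels: pd.Series, clinical: ClinicalTable) -> dict:
    """Name the two clusters by prognosis: worse median survival -> "A".

    When a cluster's KM median is not reached, restricted mean survival over
    the observed follow-up is used instead. Ties go to the smaller original
    cluster index.
    """
    labels = pd.Series(labels)
    clin = clinical.aligned_to(labels.index).table
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"prognostic naming expects exactly 2 clusters, got {uniq}")
    med = {}
    for c in uniq:
        members = labels.index[(labels == c).to_numpy()]
        med[c] = km_median_or_rmst(
            clin.loc[members, "os_time"], clin.loc[members, "os_event"]
        )
    worse = min(uniq, key=lambda c: (med[c], uniq.index(c)))
    better = [c for c in uniq if c != worse][0]
    return {worse: "A", better: "B"}


def apply_cluster_names(labels: pd.Series, mapping: dict) -> pd.Series:
    return labels.map(mapping).rename("m6a_cluster")
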