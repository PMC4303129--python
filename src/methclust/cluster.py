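"""Subsampled k-means consensus clustering of tumors.

The procedure: for each candidate k, repeatedly subsample 80% of tumors,
run k-means (squared-Euclidean objective) on their variant-probe β
profiles, and tally for each tumor pair the fraction of co-sampled runs in
which they landed in the same cluster.  Final labels come from
average-linkage hierarchical clustering of the dissimilarity
1 − consensus; k is chosen as the largest value whose least-cohesive
cluster still has mean within-cluster consensus ≥ 0.9.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency, kruskal
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ConsensusKMeans",
    "build_consensus",
    "consensus_assign",
    "cluster_consensus",
    "select_k",
    "summarize_clusters",
]

logger = logging.getLogger(__name__)


def build_consensus(
    X: np.ndarray,
    k: int,
    n_iter: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    return_iterations: bool = False,
):
    """Consensus matrix over subsampled k-means runs.

    Parameters
    ----------
    X : array, tumors x features
        β values of the variant probes (untransformed).
    k : int
        Number of k-means clusters per run; must not exceed the subsample size.
    return_iterations : bool
        Also return the per-iteration (subsample index, labels) pairs, used
        by the brute-force tally oracle in the test suite.

    Entry (i, j) is (#runs where i and j co-clustered) / (#runs where both
    were sampled).  Pairs never co-sampled are imputed as 0 with a warning.
    The diagonal is 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    m = int(np.floor(subsample_frac * n))
    if k > m:
        raise ValueError(f"k={k} exceeds subsample size {m}")
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    iterations = []
    for _ in range(n_iter):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            max_iter=300,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        labels = km.fit_predict(X[idx])
        co = (labels[:, None] == labels[None, :]).astype(float)
        together[np.ix_(idx, idx)] += co
        sampled[np.ix_(idx, idx)] += 1.0
        if return_iterations:
            iterations.append((idx.copy(), labels.copy()))
    never = sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{int(never.sum() // 2)} tumor pairs never co-sampled; consensus imputed as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.where(sampled == 0, 1, sampled), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0
    if return_iterations:
        return consensus, iterations
    return consensus


def consensus_assign(consensus: np.ndarray, k: int) -> np.ndarray:
    """Final cluster labels from a consensus matrix.

    Average-linkage hierarchical clustering on 1 − consensus, cut at k;
    labels 1..k are renumbered by decreasing cluster size (ties broken by
    first occurrence) for reproducible reporting.
    """
    consensus = np.asarray(consensus, dtype=float)
    n = consensus.shape[0]
    if k == 1:
        return np.ones(n, dtype=int)
    dissim = 1.0 - consensus
    np.fill_diagonal(dissim, 0.0)
    off_diag = dissim[~np.eye(n, dtype=bool)]
    if n > 1 and np.allclose(off_diag, off_diag[0]):
        warnings.warn("degenerate consensus matrix (all entries equal)", stacklevel=2)
    Z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber by decreasing size
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], np.argmax(raw == c)))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap[c] for c in raw], dtype=int)


def cluster_consensus(consensus: np.ndarray, assignment: np.ndarray) -> dict[int, float]:
    """Mean within-cluster consensus over unordered member pairs (singletons -> 1)."""
    consensus = np.asarray(consensus, dtype=float)
    assignment = np.asarray(assignment)
    out: dict[int, float] = {}
    for c in np.unique(assignment):
        members = np.where(assignment == c)[0]
        if len(members) < 2:
            out[int(c)] = 1.0
            continue
        sub = consensus[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        out[int(c)] = float(sub[iu].mean())
    return out


def select_k(cluster_consensus_by_k: dict[int, dict[int, float]], threshold: float = 0.9) -> int:
    """Largest k whose minimum per-cluster consensus is >= threshold (else 1)."""
    qualifying = [
        k
        for k, cc in cluster_consensus_by_k.items()
        if cc and min(cc.values()) >= threshold
    ]
    if not qualifying:
        warnings.warn("no k reached the cluster-consensus threshold; returning k=1", stacklevel=2)
        return 1
    return max(qualifying)


class ConsensusKMeans(ClusterMixin, BaseEstimator):
    """Consensus clustering estimator (sklearn interface).

    ``fit(X)`` expects tumors as rows and variant-probe β values as
    columns.  For each k in ``k_range`` it builds a consensus matrix over
    ``n_iter`` subsampled k-means runs, derives labels hierarchically, and
    picks the largest k whose every cluster has mean within-cluster
    consensus ≥ ``consensus_threshold``.

    Attributes (after fit)
    ----------------------
    consensus_matrices_ : dict[int, ndarray]
    labels_per_k_ : dict[int, ndarray]
    cluster_consensus_ : dict[int, dict[int, float]]
    best_k_ : int
    labels_ : ndarray of the chosen k's labels (1-based)
    """

    def __init__(
        self,
        k_range=tuple(range(2, 11)),
        n_iter: int = 100,
        subsample_frac: float = 0.8,
        consensus_threshold: float = 0.9,
        random_state: int = 0,
    ):
        self.k_range = k_range
        self.n_iter = n_iter
        self.subsample_frac = subsample_frac
        self.consensus_threshold = consensus_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        index = X.index if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be 2-D with at least 2 variant probes")
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        self.consensus_matrices_ = {}
        self.labels_per_k_ = {}
        self.cluster_consensus_ = {}
        for k in self.k_range:
            if k > int(np.floor(self.subsample_frac * n)):
                logger.info("skipping k=%d: exceeds subsample size", k)
                continue
            seed = int(rng.integers(0, 2**31 - 1))
            cm = build_consensus(
                X, k, n_iter=self.n_iter, subsample_frac=self.subsample_frac, seed=seed
            )
            labels = consensus_assign(cm, k)
            self.consensus_matrices_[k] = cm
            self.labels_per_k_[k] = labels
            self.cluster_consensus_[k] = cluster_consensus(cm, labels)
        self.best_k_ = select_k(self.cluster_consensus_, self.consensus_threshold)
        if self.best_k_ in self.labels_per_k_:
            self.labels_ = self.labels_per_k_[self.best_k_]
        else:  # fallback k=1
            self.labels_ = np.ones(n, dtype=int)
        self.sample_index_ = index
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def assignment_series(self) -> pd.Series:
        check_is_fitted(self, "labels_")
        return pd.Series(self.labels_, index=self.sample_index_, name="cluster")


def summarize_clusters(
    beta_subset: pd.DataFrame,
    assignment: pd.Series,
    annotation: pd.DataFrame,
    categorical=(),
    continuous=(),
) -> dict:
    """Per-cluster mean β plus cluster x covariate association summaries.

    ``beta_subset`` is probes x tumors (variant probes).  Categorical
    covariates get a contingency table with a chi-square test (no
    continuity correction); continuous covariates get a Kruskal-Wallis
    test across clusters.
    """
    assignment = assignment.reindex(beta_subset.columns)
    if annotation.index.intersection(assignment.index).size < len(assignment):
        raise ValueError("annotation does not cover all tumors")
    mean_beta = {
        int(c): float(beta_subset.loc[:, assignment.index[assignment == c]].to_numpy().mean())
        for c in sorted(assignment.unique())
    }
    crosstabs: dict[str, pd.DataFrame] = {}
    pvalues: dict[str, float] = {}
    ann = annotation.loc[assignment.index]
    for cov in categorical:
        tab = pd.crosstab(ann[cov], assignment)
        crosstabs[cov] = tab
        if tab.shape[0] > 1 and tab.shape[1] > 1:
            stat, p, _, _ = chi2_contingency(tab.to_numpy(), correction=False)
            pvalues[cov] = float(p)
        else:
            pvalues[cov] = np.nan
    for cov in continuous:
        groups = [
            ann.loc[assignment == c, cov].dropna().to_numpy()
            for c in sorted(assignment.unique())
        ]
        groups = [g for g in groups if len(g)]
        if len(groups) >= 2:
            stat, p = kruskal(*groups)
            pvalues[cov] = float(p)
        else:
            pvalues[cov] = np.nan
    return {"mean_beta": mean_beta, "crosstabs": crosstabs, "pvalues": pvalues}
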