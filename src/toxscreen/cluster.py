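"""Profile clustering: PCA of slice scores, k-means, cluster mean profiles.

The slice-score matrix of a process model is decomposed with PCA (columns
centered, not rescaled -- component scores already live on a common
[0, weight] scale); all components explaining >= 5% of the overall variance
are retained, and k-means (Lloyd, iteration cap 10,000) is run on the
projected coordinates with the number of clusters defaulting to the number
of retained components.  Because a single k-means run is sensitive to its
initialization, several seeded restarts are run and the solution with the
lowest within-cluster sum of squares kept.  Each cluster is then summarized
by its mean slice-score profile and ranked by its mean overall score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "PCABasis",
    "ClusterResult",
    "ToxPiProfileClusterer",
    "pca_reduce",
    "kmeans_cluster",
    "cluster_profiles",
]

DEFAULT_VARIANCE_THRESHOLD = 0.05
DEFAULT_MAX_ITERATIONS = 10_000
DEFAULT_RESTARTS = 10


@dataclass(frozen=True)
class PCABasis:
    """Retained principal-component basis of a slice-score matrix."""

    loadings: np.ndarray  # (n_retained, n_slices), rows are components
    explained_variance_fraction: np.ndarray  # all components, decreasing
    retained_indices: tuple[int, ...]  # components with fraction >= threshold


@dataclass
class ClusterResult:
    """k-means outcome on retained-PC coordinates."""

    assignments: pd.Series  # chemical_id -> integer cluster label
    centroids: np.ndarray  # (k, n_retained_pcs)
    seed: Optional[int]
    n_iterations_used: int
    inertia: float
    mean_profile: Optional[pd.DataFrame] = None  # filled by cluster_profiles


def pca_reduce(
    slice_scores: pd.DataFrame, threshold: float = DEFAULT_VARIANCE_THRESHOLD
) -> tuple[PCABasis, pd.DataFrame]:
    """Center, decompose, and keep components explaining >= ``threshold``.

    Returns the basis plus the chemicals projected onto the retained
    components.  A matrix with zero total variance cannot be decomposed and
    raises; a threshold no component reaches also raises (nothing to project
    onto).
    """
    if slice_scores.shape[0] < 2 or slice_scores.shape[1] < 2:
        raise ValueError("need at least 2 chemicals and 2 slices")
    values = slice_scores.to_numpy(dtype=float)
    if np.allclose(values.var(axis=0), 0.0):
        raise ValueError("slice-score matrix has zero variance; nothing to decompose")
    pca = PCA(n_components=min(values.shape), svd_solver="full")
    coords_all = pca.fit_transform(values)
    fractions = pca.explained_variance_ratio_
    retained = tuple(int(i) for i in np.flatnonzero(fractions >= threshold))
    if not retained:
        raise ValueError(
            f"no principal component explains >= {threshold:.0%} of the variance"
        )
    basis = PCABasis(
        loadings=pca.components_[list(retained)],
        explained_variance_fraction=fractions,
        retained_indices=retained,
    )
    coords = pd.DataFrame(
        coords_all[:, list(retained)],
        index=slice_scores.index,
        columns=[f"PC{i + 1}" for i in retained],
    )
    return basis, coords


def kmeans_cluster(
    coords: pd.DataFrame,
    k_max: int,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    seed: Optional[int] = None,
    restarts: int = DEFAULT_RESTARTS,
) -> ClusterResult:
    """Seeded Lloyd k-means on projected coordinates; deterministic given seed."""
    n = len(coords)
    if not 1 <= k_max <= n:
        raise ValueError(f"k_max must be in [1, {n}], got {k_max}")
    km = KMeans(
        n_clusters=k_max,
        n_init=restarts,
        max_iter=max_iterations,
        random_state=seed,
        algorithm="lloyd",
    )
    labels = km.fit_predict(coords.to_numpy(dtype=float))
    return ClusterResult(
        assignments=pd.Series(labels, index=coords.index, name="cluster"),
        centroids=km.cluster_centers_,
        seed=seed,
        n_iterations_used=int(km.n_iter_),
        inertia=float(km.inertia_),
    )


def cluster_profiles(result: ClusterResult, slice_scores: pd.DataFrame) -> pd.DataFrame:
    """Mean slice-score profile and size per cluster, by mean overall score.

    Rows are clusters ordered by descending mean overall ToxPi score, with
    columns ``size``, ``mean_overall`` and one column per slice.
    """
    if not result.assignments.index.equals(slice_scores.index):
        slice_scores = slice_scores.loc[result.assignments.index]
    grouped = slice_scores.groupby(result.assignments)
    profile = grouped.mean()
    profile.insert(0, "mean_overall", profile.sum(axis=1))
    profile.insert(0, "size", grouped.size())
    profile = profile.sort_values("mean_overall", ascending=False)
    profile.index.name = "cluster"
    result.mean_profile = profile
    return profile


class ToxPiProfileClusterer(BaseEstimator):
    """PCA + k-means pipeline over a model's slice-score matrix.

    Parameters
    ----------
    threshold : float
        Minimum explained-variance fraction for a component to be retained.
    k : int or "auto"
        Cluster count; "auto" uses the number of retained components.
    max_iter, restarts, random_state
        Lloyd iteration cap, number of seeded restarts (best inertia kept),
        and the seed making the whole fit deterministic.

    Attributes (after fit)
    ----------------------
    basis_ : PCABasis
    coords_ : DataFrame of retained-PC coordinates
    labels_ : ndarray of cluster labels
    result_ : ClusterResult
    profiles_ : DataFrame from :func:`cluster_profiles`
    """

    def __init__(
        self,
        threshold: float = DEFAULT_VARIANCE_THRESHOLD,
        k: Union[int, str] = "auto",
        max_iter: int = DEFAULT_MAX_ITERATIONS,
        restarts: int = DEFAULT_RESTARTS,
        random_state: Optional[int] = None,
    ):
        self.threshold = threshold
        self.k = k
        self.max_iter = max_iter
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "ToxPiProfileClusterer":
        self.basis_, self.coords_ = pca_reduce(X, self.threshold)
        k = len(self.basis_.retained_indices) if self.k == "auto" else int(self.k)
        k = min(k, len(X))
        self.result_ = kmeans_cluster(
            self.coords_,
            k_max=k,
            max_iterations=self.max_iter,
            seed=self.random_state,
            restarts=self.restarts,
        )
        self.labels_ = self.result_.assignments.to_numpy()
        self.profiles_ = cluster_profiles(self.result_, X)
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_
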