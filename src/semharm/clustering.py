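"""Spherical k-means with cosine distance, plus cluster-count diagnostics.

Spherical k-means places both data points and centroids on the unit sphere
and alternates between assigning each point to the centroid with the
smallest cosine distance (1 − cosine similarity) and replacing each centroid
by the L2-normalized mean of its members. The objective (inertia) is

    Σ_i (1 − cos(x_i, c_label(i))),

which the update step never increases. Model selection across k uses the
elbow of the inertia curve together with the Calinski–Harabasz index and the
mean silhouette coefficient, all computed from the same fitted model per k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
from scipy.spatial.distance import cdist

from ._utils import knee_point, l2_normalize_rows

logger = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    centroids: np.ndarray  # k×d, unit-norm rows
    labels: np.ndarray  # length-n ints in [0, k)
    inertia: float
    k: int
    max_iter: int
    init_method: str
    seed: int | None
    converged: bool
    n_iter: int = 0
    inertia_history: list[float] = field(default_factory=list)
    empty_cluster_events: int = 0


@dataclass
class SelectionDiagnostics:
    """Per-k model-selection metrics (inertia, CH index, mean silhouette)."""

    table: "object"  # pandas.DataFrame with columns k, inertia, calinski_harabasz, mean_silhouette

    def knee_k(self) -> int:
        frame = self.table
        idx = knee_point(frame["k"].to_numpy(), frame["inertia"].to_numpy())
        return int(frame["k"].iloc[idx])


def _init_centroids(X: np.ndarray, k: int, init: str, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    if init == "random":
        idx = rng.choice(n, size=k, replace=False)
        return X[idx].copy()
    if init == "cosine_plus_plus":
        # k-means++ seeding with D(x) = cosine distance to the nearest seed
        idx = [int(rng.integers(n))]
        dist = 1.0 - X @ X[idx[0]]
        for _ in range(1, k):
            d = np.clip(dist, 0.0, None)
            total = d.sum()
            if total <= 0:
                choice = int(rng.integers(n))
            else:
                choice = int(rng.choice(n, p=d / total))
            idx.append(choice)
            dist = np.minimum(dist, 1.0 - X @ X[choice])
        return X[np.array(idx)].copy()
    if init == "similar_cut_like":
        # fast farthest-first flavor: random first seed, then repeatedly take
        # the point whose maximum similarity to the chosen seeds is smallest
        idx = [int(rng.integers(n))]
        max_sim = X @ X[idx[0]]
        for _ in range(1, k):
            cand = int(np.argmin(max_sim))
            idx.append(cand)
            max_sim = np.maximum(max_sim, X @ X[cand])
        return X[np.array(idx)].copy()
    raise ValueError(f"unknown init method {init!r}")


def _apply_sparsity(
    centroids: np.ndarray, X, labels: np.ndarray, minimum_df_factor: float
) -> np.ndarray:
    """Zero centroid coordinates supported by too few member documents.

    Only meaningful for non-negative sparse term-frequency inputs; mirrors a
    minimum-document-frequency filter (coordinates present in fewer than
    ``minimum_df_factor`` of the cluster's documents are dropped before
    renormalization).
    """
    Xc = scipy.sparse.csr_matrix(X)
    support = Xc > 0
    for j in range(centroids.shape[0]):
        members = np.flatnonzero(labels == j)
        if members.size == 0:
            continue
        df = np.asarray(support[members].sum(axis=0)).ravel() / members.size
        centroids[j, df < minimum_df_factor] = 0.0
        norm = np.linalg.norm(centroids[j])
        if norm > 0:
            centroids[j] /= norm
    return centroids


def _single_run(
    X: np.ndarray,
    k: int,
    max_iter: int,
    init: str,
    rng: np.random.Generator,
    sparsity: dict | None,
    X_sparse,
) -> ClusterModel:
    n = X.shape[0]
    centroids = _init_centroids(X, k, init, rng)
    labels = np.full(n, -1, dtype=int)
    history: list[float] = []
    empty_events = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sims = X @ centroids.T
        new_labels = np.argmax(sims, axis=1)  # argmax takes the lowest index on ties
        # empty-cluster repair: reseed with the point farthest from its centroid
        for j in range(k):
            if not np.any(new_labels == j):
                assigned_sims = sims[np.arange(n), new_labels]
                farthest = int(np.argmin(assigned_sims))
                new_labels[farthest] = j
                sims[farthest, :] = np.inf  # keep it out of later repairs this pass
                empty_events += 1
                logger.debug("reseeded empty cluster %d with point %d", j, farthest)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            mean = members.mean(axis=0)
            norm = np.linalg.norm(mean)
            if norm > 0:
                centroids[j] = mean / norm
            # a vanishing mean leaves the previous centroid in place
        if sparsity is not None and X_sparse is not None:
            centroids = _apply_sparsity(centroids, X_sparse, labels, sparsity["minimum_df_factor"])
        history.append(float(np.sum(1.0 - (X @ centroids.T)[np.arange(n), labels])))
    inertia = float(np.sum(1.0 - (X @ centroids.T)[np.arange(n), labels]))
    return ClusterModel(
        centroids=centroids,
        labels=labels,
        inertia=inertia,
        k=k,
        max_iter=max_iter,
        init_method=init,
        seed=None,
        converged=converged,
        n_iter=it,
        inertia_history=history,
        empty_cluster_events=empty_events,
    )


def spherical_kmeans(
    X: np.ndarray,
    k: int,
    max_iter: int = 10,
    init: str = "cosine_plus_plus",
    restarts: int = 1,
    seed: int | None = None,
    sparsity: dict | None = None,
) -> ClusterModel:
    """Fit spherical k-means; return the lowest-inertia model over restarts.

    Rows of ``X`` are L2-normalized internally, so cluster assignments are
    invariant under positive rescaling of the inputs. Assignment ties go to
    the lowest centroid index; an emptied cluster is re-seeded with the point
    farthest (largest cosine distance) from its current centroid. ``sparsity``
    (``{"minimum_df_factor": f}``) applies a minimum-document-frequency
    centroid projection when ``X`` is non-negative and sparse, and is a
    logged no-op on dense inputs.
    """
    X_sparse = None
    if scipy.sparse.issparse(X):
        if sparsity is not None and X.min() >= 0:
            X_sparse = X
        X = np.asarray(X.todense(), dtype=float)
    elif sparsity is not None:
        logger.warning("sparsity projection requested on dense input; no-op")
        sparsity = None
    X = l2_normalize_rows(np.asarray(X, dtype=float))
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n; got k={k}, n={n}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for _ in range(restarts):
        model = _single_run(X, k, max_iter, init, rng, sparsity, X_sparse)
        if best is None or model.inertia < best.inertia:
            best = model
    assert best is not None
    best.seed = seed
    return best


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz index [B/(k−1)] / [W/(n−k)] on the given rows.

    B is the centroid-weighted between-cluster sum of squared Euclidean
    distances from the grand mean; W the within-cluster sum of squares.
    Returns +inf (flagged in the log) when W vanishes.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValueError("Calinski-Harabasz requires at least 2 clusters")
    if n <= k:
        raise ValueError("need n > k")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for j in uniq:
        members = X[labels == j]
        if members.size == 0:
            raise ValueError(f"cluster {j} is empty")
        c = members.mean(axis=0)
        B += members.shape[0] * float(np.sum((c - grand) ** 2))
        W += float(np.sum((members - c) ** 2))
    if W == 0.0:
        logger.warning("zero within-cluster scatter; CH index is infinite")
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def silhouette_mean(X: np.ndarray, labels: np.ndarray, metric: str = "cosine") -> float:
    """Mean silhouette coefficient (b−a)/max(a,b) over all points.

    ``a`` is the mean distance to the point's own cluster (self excluded),
    ``b`` the smallest mean distance to any other cluster. Points in
    singleton clusters contribute 0 by convention.
    """
    if metric not in ("cosine", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(X, X, metric=metric)
    n = X.shape[0]
    scores = np.zeros(n)
    sizes = {j: int(np.sum(labels == j)) for j in uniq}
    for i in range(n):
        li = labels[i]
        if sizes[li] == 1:
            continue  # singleton convention: silhouette 0
        a = D[i, labels == li].sum() / (sizes[li] - 1)
        b = min(D[i, labels == j].mean() for j in uniq if j != li)
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def elbow_scan(
    X: np.ndarray,
    k_grid: list[int],
    max_iter: int = 10,
    init: str = "cosine_plus_plus",
    restarts: int = 1,
    seed: int | None = None,
) -> SelectionDiagnostics:
    """Fit one model per k and tabulate inertia, CH and mean silhouette.

    All three metrics for a given k come from the same fitted model, computed
    on the normalized rows; per-k seeds derive deterministically from the
    master seed.
    """
    import pandas as pd

    if list(k_grid) != sorted(set(k_grid)):
        raise ValueError("k_grid must be strictly increasing")
    Xn = l2_normalize_rows(np.asarray(X, dtype=float))
    if max(k_grid) > Xn.shape[0]:
        raise ValueError("max(k_grid) exceeds the number of points")
    rows = []
    for j, k in enumerate(k_grid):
        sub_seed = None if seed is None else seed + j
        model = spherical_kmeans(
            Xn, k, max_iter=max_iter, init=init, restarts=restarts, seed=sub_seed
        )
        ch = calinski_harabasz(Xn, model.labels) if k >= 2 else float("nan")
        sil = silhouette_mean(Xn, model.labels, metric="cosine") if k >= 2 else float("nan")
        rows.append({"k": k, "inertia": model.inertia, "calinski_harabasz": ch, "mean_silhouette": sil})
    return SelectionDiagnostics(table=pd.DataFrame(rows))
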