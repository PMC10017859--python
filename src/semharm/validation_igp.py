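"""In-Group Proportion (IGP) cluster-reproducibility validation.

The IGP (Kapp & Tibshirani) asks whether cluster centers fitted on a
training set predict co-membership in an independent test set. Each test
point is assigned to its nearest training centroid; for a cluster j,

    IGP_j = proportion of test points assigned to j whose nearest *test*
            neighbor (self excluded) is also assigned to j.

Values near 1 mean the cluster reappears coherently in independent data.
Clusters holding fewer than two test points have no defined proportion and
are excluded from summaries (and logged). Replicated runs re-partition the
data, refit the clustering on the training half, and summarize the defined
per-cluster values per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._utils import l2_normalize_rows
from .clustering import ClusterModel, spherical_kmeans
from .corpus_io import partition_records

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("Median", "IQR", "Mean", "SD", "Q1", "Q3", "Range")


@dataclass
class IGPReport:
    """Per-cluster IGP values with summary statistics over defined clusters."""

    per_cluster_igp: dict[int, float]  # undefined clusters map to nan
    summary: dict[str, float]
    n_train: int
    n_test: int
    seed: int | None = None

    @property
    def defined_values(self) -> np.ndarray:
        vals = np.array([v for v in self.per_cluster_igp.values() if not np.isnan(v)])
        return vals


def _distance_matrix(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cosine":
        return 1.0 - l2_normalize_rows(A) @ l2_normalize_rows(B).T
    if metric == "one_minus_pearson":
        return cdist(A, B, metric="correlation")
    raise ValueError(f"unknown metric {metric!r}")


def classify_to_centroids(
    X_test: np.ndarray, centroids: np.ndarray, metric: str = "cosine"
) -> np.ndarray:
    """Assign each test point to its nearest centroid (ties → lowest index)."""
    X_test = np.asarray(X_test, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if X_test.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: points are {X_test.shape[1]}-d, centroids {centroids.shape[1]}-d"
        )
    D = _distance_matrix(X_test, centroids, metric)
    return np.argmin(D, axis=1)  # argmin takes the lowest index on ties


def summarize(values: np.ndarray) -> dict[str, float]:
    """Median/IQR/Mean/SD/Q1/Q3/Range of the defined per-cluster values.

    Quartiles use linear-interpolation quantiles; SD is the sample standard
    deviation (ddof=1, 0 for a single value)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return {c: float("nan") for c in SUMMARY_COLUMNS}
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return {
        "Median": float(med),
        "IQR": float(q3 - q1),
        "Mean": float(values.mean()),
        "SD": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "Q1": float(q1),
        "Q3": float(q3),
        "Range": float(values.max() - values.min()),
    }


def igp(
    X_test: np.ndarray,
    centroid_labels: np.ndarray,
    metric: str = "cosine",
    n_train: int = 0,
    seed: int | None = None,
) -> IGPReport:
    """Per-cluster IGP of test points given their nearest-centroid labels."""
    X_test = np.asarray(X_test, dtype=float)
    centroid_labels = np.asarray(centroid_labels)
    if X_test.shape[0] != centroid_labels.shape[0]:
        raise ValueError("labels must match the number of test points")
    n = X_test.shape[0]
    if n < 2:
        raise ValueError("IGP requires at least 2 test points")
    D = _distance_matrix(X_test, X_test, metric)
    np.fill_diagonal(D, np.inf)
    nearest = np.argmin(D, axis=1)
    per_cluster: dict[int, float] = {}
    for j in np.unique(centroid_labels):
        members = np.flatnonzero(centroid_labels == j)
        if members.size < 2:
            logger.info("cluster %s has %d test point(s); IGP undefined", j, members.size)
            per_cluster[int(j)] = float("nan")
            continue
        per_cluster[int(j)] = float(
            np.mean(centroid_labels[nearest[members]] == j)
        )
    defined = np.array([v for v in per_cluster.values() if not np.isnan(v)])
    return IGPReport(
        per_cluster_igp=per_cluster,
        summary=summarize(defined),
        n_train=n_train,
        n_test=n,
        seed=seed,
    )


def replicate_igp(
    X: np.ndarray,
    k: int,
    n_runs: int,
    train_size: int,
    seed: int,
    metric: str = "cosine",
    max_iter: int = 10,
    init: str = "cosine_plus_plus",
    restarts: int = 10,
):
    """Repeated partition → fit → classify → IGP runs with a per-run summary.

    Returns ``(reports, table)`` where ``table`` is a pandas DataFrame with
    one row per run and columns Iteration, Median, IQR, Mean, SD, Q1, Q3,
    Range. Deterministic for a fixed master seed (per-run seeds derive from
    it).
    """
    import pandas as pd

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    ids = [str(i) for i in range(n)]
    reports: list[IGPReport] = []
    rows = []
    for run in range(n_runs):
        run_seed = seed + run
        part = partition_records(ids, train_size, seed=run_seed)
        train_idx = np.array(sorted(int(i) for i in part.train_ids))
        test_idx = np.array(sorted(int(i) for i in part.test_ids))
        model: ClusterModel = spherical_kmeans(
            X[train_idx], k, max_iter=max_iter, init=init, restarts=restarts, seed=run_seed
        )
        test_labels = classify_to_centroids(X[test_idx], model.centroids, metric=metric)
        report = igp(X[test_idx], test_labels, metric=metric, n_train=train_idx.size, seed=run_seed)
        reports.append(report)
        rows.append({"Iteration": run, **report.summary})
    return reports, pd.DataFrame(rows)
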