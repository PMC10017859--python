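"""Locally linear embedding (LLE) and the reconstruction-error dimension sweep.

LLE (Roweis & Saul) reconstructs each point from its K nearest neighbors with
weights that sum to one, then finds low-dimensional coordinates Y preserving
those weights. The quality of an embedding is measured by the reconstruction
error

    Φ(Y) = Σ_i ‖Y_i − Σ_j W_ij Y_j‖²,

which equals the sum of the retained eigenvalues of M = (I−W)ᵀ(I−W) when the
coordinates are the bottom eigenvectors of M (the constant eigenvector
discarded). The sweep re-fits LLE over a grid of output dimensions on
replicated random subsamples and tabulates Φ statistics per dimension, the
diagnostic used to choose the reduced dimension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from scipy.spatial.distance import cdist

from ._utils import knee_point

logger = logging.getLogger(__name__)

#: Tikhonov factor r in the local-Gram conditioner r·trace(G)/K.
DEFAULT_REG = 1e-3

#: Above this n the bottom eigenpairs come from an iterative shift-invert
#: solver instead of a dense symmetric factorization.
DENSE_EIGH_LIMIT = 2000


@dataclass
class ReductionResult:
    """Embedded coordinates with their reconstruction error and parameters."""

    Y: np.ndarray
    phi: float
    K: int
    d: int
    seed: int | None = None
    W: scipy.sparse.csr_matrix | None = None


@dataclass
class SweepTable:
    """Per-dimension Φ statistics over replicated subsamples."""

    table: "object"  # pandas.DataFrame with the columns below
    replications: int

    COLUMNS = ("d", "mean_phi", "min_phi", "max_phi", "median_phi", "iqr_phi", "sd_phi")


def _nearest_neighbors(X: np.ndarray, K: int) -> np.ndarray:
    """Indices of the K nearest neighbors (Euclidean, self excluded) per row.

    Ties are broken by lowest index via a stable argsort, so the neighbor
    graph is reproducible on degenerate data.
    """
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :K]


def barycenter_weights(X: np.ndarray, neighbors: np.ndarray, reg: float = DEFAULT_REG) -> np.ndarray:
    """Reconstruction weights: per point, minimize ‖X_i − Σ_j w_j X_nbr_j‖²
    subject to Σ_j w_j = 1, with the local Gram matrix conditioned by adding
    reg·trace(G)/K (or reg itself when the trace vanishes) to its diagonal."""
    n, K = neighbors.shape
    W = np.empty((n, K))
    ones = np.ones(K)
    for i in range(n):
        C = X[neighbors[i]] - X[i]
        G = C @ C.T
        trace = np.trace(G)
        G.flat[:: K + 1] += reg * trace / K if trace > 0 else reg
        try:
            w = scipy.linalg.solve(G, ones, assume_a="pos")
        except scipy.linalg.LinAlgError:
            logger.warning("singular local Gram at point %d despite regularization", i)
            w = np.linalg.lstsq(G, ones, rcond=None)[0]
        W[i] = w / w.sum()
    return W


def _weight_matrix(n: int, neighbors: np.ndarray, weights: np.ndarray) -> scipy.sparse.csr_matrix:
    K = neighbors.shape[1]
    indptr = np.arange(0, n * K + 1, K)
    return scipy.sparse.csr_matrix((weights.ravel(), neighbors.ravel(), indptr), shape=(n, n))


def reconstruction_error(W: scipy.sparse.spmatrix, Y: np.ndarray) -> float:
    """Φ(Y) = Σ_i ‖Y_i − Σ_j W_ij Y_j‖²."""
    R = Y - W @ Y
    return float(np.sum(R * R))


def lle_fit(
    X: np.ndarray,
    K: int = 5,
    d: int = 2,
    reg: float = DEFAULT_REG,
    seed: int | None = None,
) -> ReductionResult:
    """Fit standard LLE and report the reconstruction error Φ(Y).

    The embedding is the bottom ``d+1`` eigenvectors of (I−W)ᵀ(I−W) with the
    constant (smallest) eigenvector discarded. Column signs are fixed by
    making each column's largest-magnitude entry positive so repeated runs
    are comparable.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    n = X.shape[0]
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if K < 1 or K >= n:
        raise ValueError(f"need 1 <= K < n; got K={K}, n={n}")
    if d < 1 or d >= n:
        raise ValueError(f"need 1 <= d < n; got d={d}, n={n}")

    neighbors = _nearest_neighbors(X, K)
    weights = barycenter_weights(X, neighbors, reg=reg)
    W = _weight_matrix(n, neighbors, weights)

    I_W = scipy.sparse.eye(n, format="csr") - W
    M = (I_W.T @ I_W).toarray()

    if n <= DENSE_EIGH_LIMIT:
        vals, vecs = scipy.linalg.eigh(M, subset_by_index=[0, d])
    else:
        # shift-invert around 0 targets the bottom of the spectrum
        vals, vecs = scipy.sparse.linalg.eigsh(
            scipy.sparse.csr_matrix(M), k=d + 1, sigma=0.0, which="LM", tol=1e-10
        )
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]

    # Discard the constant direction. When the neighbor graph is disconnected
    # the null space of M has multiplicity and the constant vector need not
    # appear as a single returned eigenvector, so instead of dropping column 0
    # we project span{1} out of the bottom (d+1)-dimensional eigenspace and
    # re-orthonormalize; Φ only depends on the retained subspace.
    ones = np.full((n, 1), 1.0 / np.sqrt(n))
    Vp = vecs - ones @ (ones.T @ vecs)
    U, S, _ = scipy.linalg.svd(Vp, full_matrices=False)
    Y = U[:, :d]
    flip = np.sign(Y[np.argmax(np.abs(Y), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    Y = Y * flip

    phi = reconstruction_error(W, Y)
    return ReductionResult(Y=Y, phi=phi, K=K, d=d, seed=seed, W=W)


def sweep_dimensions(
    X: np.ndarray,
    K: int,
    d_grid: list[int],
    replications: int,
    subsample_size: int,
    seed: int,
    reg: float = DEFAULT_REG,
) -> SweepTable:
    """Replicated Φ(Y) sweep over candidate output dimensions.

    Each replication draws a fresh random subsample (without replacement) of
    ``subsample_size`` points and fits LLE at every d in the grid; per-d
    statistics are aggregated across replications. Deterministic for a fixed
    seed.
    """
    import pandas as pd

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not d_grid:
        raise ValueError("d_grid is empty")
    if subsample_size > n:
        raise ValueError(f"subsample_size {subsample_size} exceeds n={n}")
    if max(d_grid) >= subsample_size:
        raise ValueError("every d in the grid must be < subsample_size")
    rng = np.random.default_rng(seed)
    phis = np.empty((replications, len(d_grid)))
    for r in range(replications):
        idx = rng.choice(n, size=subsample_size, replace=False)
        Xs = X[idx]
        for j, d in enumerate(d_grid):
            phis[r, j] = lle_fit(Xs, K=K, d=d, reg=reg).phi
    q1 = np.quantile(phis, 0.25, axis=0)
    q3 = np.quantile(phis, 0.75, axis=0)
    frame = pd.DataFrame(
        {
            "d": list(d_grid),
            "mean_phi": phis.mean(axis=0),
            "min_phi": phis.min(axis=0),
            "max_phi": phis.max(axis=0),
            "median_phi": np.median(phis, axis=0),
            "iqr_phi": q3 - q1,
            "sd_phi": phis.std(axis=0, ddof=1) if replications > 1 else np.zeros(len(d_grid)),
            "replications": replications,
        }
    )
    return SweepTable(table=frame, replications=replications)


def select_dimension(table: SweepTable, mode: str = "manual", manual_d: int | None = None) -> int:
    """Choose the output dimension from a sweep table.

    ``manual`` returns the user-supplied d (it must appear in the table);
    ``knee`` returns the d whose (d, mean Φ) point lies farthest from the
    chord joining the curve's endpoints.
    """
    frame = table.table
    if len(frame) == 0:
        raise ValueError("sweep table is empty")
    if mode == "manual":
        if manual_d is None or manual_d not in set(frame["d"]):
            raise ValueError(f"manual dimension {manual_d!r} not present in the sweep table")
        return int(manual_d)
    if mode == "knee":
        idx = knee_point(frame["d"].to_numpy(), frame["mean_phi"].to_numpy())
        return int(frame["d"].iloc[idx])
    raise ValueError(f"unknown selection mode {mode!r}")
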