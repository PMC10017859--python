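"""Shared numeric and bookkeeping helpers."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np


def l2_normalize_rows(X: np.ndarray, copy: bool = True) -> np.ndarray:
    """Scale each row of ``X`` to unit Euclidean norm.

    Raises ``ValueError`` if any row is zero (direction undefined).
    """
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"row {bad} has zero norm; cannot normalize")
    out = X / norms[:, None]
    return out.copy() if copy and out is X else out


def knee_point(x: np.ndarray, y: np.ndarray) -> int:
    """Index of the knee of a curve by maximum perpendicular distance to the
    chord joining the endpoints. Returns 0 for single-point curves."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("x and y must be non-empty and of equal length")
    if x.size < 3:
        return 0
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return 0
    pts = np.stack([x, y], axis=1) - p0
    # unsigned area of the parallelogram / chord length = point-chord distance
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return int(np.argmax(dist))


def derive_seed(master_seed: int, *spawn_key: int) -> int:
    """Derive an independent 31-bit child seed from a master seed.

    Uses numpy's SeedSequence spawning so per-stage streams are independent
    and each stage can be re-run in isolation from the manifest.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(spawn_key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
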