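"""Text encoders and cosine-similarity primitives.

Questionnaire items and taxonomy strings are compared in an inner-product
space: each string becomes a fixed-length vector, L2-normalized so cosine
similarity reduces to a dot product everywhere downstream.

Two encoder backends satisfy the same contract:

* :class:`HashedNgramEncoder` — a deterministic, dependency-free fallback:
  hashed character n-gram (3–5) term frequencies followed by a seeded
  Gaussian random projection. It preserves the property the pipeline needs
  (near-duplicate strings embed close together) without any model download.
* :class:`SentenceTransformerEncoder` — optional plug-in for a pretrained
  sentence encoder (e.g. a 768-dimensional MPNet model); requires the
  ``sentence-transformers`` package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from ._utils import l2_normalize_rows


@dataclass
class EmbeddingMatrix:
    """n×D matrix of item embeddings with row identifiers."""

    ids: list[str]
    vectors: np.ndarray
    encoder_tag: str
    unit_norm: bool = True

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-d matrix")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("number of ids must equal number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids")
        if self.unit_norm:
            norms = np.linalg.norm(self.vectors, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("unit_norm set but some row norms deviate from 1")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


class Encoder(Protocol):
    """Encoder contract: map strings to an (n, dim) float array."""

    tag: str
    dim: int

    def encode(self, texts: Sequence[str]) -> np.ndarray: ...


class HashedNgramEncoder:
    """Deterministic fallback encoder.

    Character n-grams (3–5, word-boundary padded) are hashed into a
    ``2**hash_bits``-dimensional term-frequency vector, then projected to
    ``dim`` dimensions with a Gaussian matrix drawn once from ``seed``.
    Identical inputs always yield identical rows; outputs are not
    L2-normalized here (normalization happens in :func:`encode_texts`).
    """

    def __init__(self, dim: int = 256, seed: int = 0, hash_bits: int = 12):
        from sklearn.feature_extraction.text import HashingVectorizer

        self.dim = int(dim)
        self.seed = int(seed)
        self._n_features = 1 << hash_bits
        self._vectorizer = HashingVectorizer(
            analyzer="char_wb",
            ngram_range=(3, 5),
            n_features=self._n_features,
            norm=None,
            alternate_sign=False,
            lowercase=True,
        )
        rng = np.random.default_rng(self.seed)
        self._projection = rng.standard_normal((self._n_features, self.dim)) / np.sqrt(self.dim)
        self.tag = f"hashed-ngram-3.5/d{self.dim}/seed{self.seed}"

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        counts = self._vectorizer.transform(texts)
        return np.asarray(counts @ self._projection)


class EncoderUnavailableError(RuntimeError):
    """The requested external encoder backend cannot be loaded."""


class SentenceTransformerEncoder:
    """Optional pretrained sentence-encoder backend (768-d for MPNet models).

    Never required by the test suite; raises :class:`EncoderUnavailableError`
    with a pointer to the fallback when the package or model is missing.
    """

    def __init__(self, model_name: str = "sentence-transformers/all-mpnet-base-v2"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:
            raise EncoderUnavailableError(
                "sentence-transformers is not installed; install the 'encoders' "
                "extra or use the built-in HashedNgramEncoder fallback"
            ) from exc
        self._model = SentenceTransformer(model_name)
        self.dim = int(self._model.get_sentence_embedding_dimension())
        self.tag = f"sentence-transformers/{model_name}"

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        return np.asarray(self._model.encode(list(texts), convert_to_numpy=True))


def encode_texts(
    texts: Sequence[str],
    backend: Encoder,
    ids: Sequence[str] | None = None,
) -> EmbeddingMatrix:
    """Encode texts into an L2-normalized :class:`EmbeddingMatrix`.

    Rows follow input order. Empty (or whitespace-only) strings are rejected
    with the offending index, since their embedding direction is undefined.
    """
    texts = list(texts)
    for i, t in enumerate(texts):
        if not isinstance(t, str) or not t.strip():
            raise ValueError(f"text at index {i} is empty")
    if ids is None:
        ids = [str(i) for i in range(len(texts))]
    vectors = np.asarray(backend.encode(texts), dtype=float)
    if vectors.shape[0] != len(texts):
        raise RuntimeError("encoder returned wrong number of rows")
    return EmbeddingMatrix(
        ids=list(ids),
        vectors=l2_normalize_rows(vectors),
        encoder_tag=backend.tag,
        unit_norm=True,
    )


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """sim(x, y) = x·y / (‖x‖‖y‖), in [−1, 1]; undefined for zero vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.dot(x, y) / (nx * ny))


def pairwise_similarity(
    A: EmbeddingMatrix | np.ndarray, B: EmbeddingMatrix | np.ndarray
) -> np.ndarray:
    """|A|×|B| matrix of cosine similarities between rows of A and rows of B."""
    Xa = A.vectors if isinstance(A, EmbeddingMatrix) else np.asarray(A, dtype=float)
    Xb = B.vectors if isinstance(B, EmbeddingMatrix) else np.asarray(B, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[None, :]
    if Xb.ndim == 1:
        Xb = Xb[None, :]
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError(f"dimension mismatch: {Xa.shape[1]} vs {Xb.shape[1]}")
    return l2_normalize_rows(Xa) @ l2_normalize_rows(Xb).T


def save_embeddings(matrix: EmbeddingMatrix, path_prefix) -> None:
    """Write vectors as TSV plus a JSON sidecar (ids, tag, dim, norm flag)."""
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    np.savetxt(prefix.with_suffix(".tsv"), matrix.vectors, delimiter="\t")
    sidecar = {
        "ids": matrix.ids,
        "encoder_tag": matrix.encoder_tag,
        "dim": matrix.dim,
        "unit_norm": matrix.unit_norm,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_embeddings(path_prefix) -> EmbeddingMatrix:
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    vectors = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return EmbeddingMatrix(
        ids=meta["ids"],
        vectors=vectors,
        encoder_tag=meta["encoder_tag"],
        unit_norm=bool(meta["unit_norm"]),
    )
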