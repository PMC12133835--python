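"""Text-embedding backends and cosine-similarity utilities.

The default backend is a deterministic hash embedding: every normalized token
maps to a fixed 64-dimensional Gaussian vector derived from a stable 64-bit
digest of (backend seed, token), and a text embeds as the unit-normalized mean
of its unique token vectors.  Texts with identical token sets therefore embed
identically, similarity grows with token overlap, and results reproduce
across processes and platforms with no model download.

A thin adapter for sentence-transformers encoders satisfies the same contract
when that library and a checkpoint are available.
"""

from __future__ import annotations

import hashlib
from typing import Protocol

import numpy as np

from .tokens import tokenize

MOCK_DIMENSION = 64


class EmbeddingBackend(Protocol):
    """Contract: ``embed`` is deterministic, unit-norm, fixed dimension."""

    name: str
    dimension: int
    deterministic: bool

    def embed(self, text: str) -> np.ndarray: ...


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Dot product of unit vectors; symmetric, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def clip01(x: float) -> float:
    """Clip a similarity to [0, 1]; negative cosine is treated as irrelevant."""
    return float(min(max(x, 0.0), 1.0))


class HashEmbeddingBackend:
    """Deterministic token-hash embedding (the default, network-free backend)."""

    def __init__(self, seed: int = 0, dimension: int = MOCK_DIMENSION):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.name = f"hash-{dimension}d"
        self.seed = int(seed)
        self.dimension = int(dimension)
        self.deterministic = True
        self._token_cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._token_cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}:{token}".encode("utf-8"), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            vec = rng.standard_normal(self.dimension)
            self._token_cache[token] = vec
        return vec

    def embed(self, text: str) -> np.ndarray:
        toks = sorted(tokenize(text).tokens)
        if not toks:
            raise ValueError("cannot embed empty text")
        mean = np.mean([self._token_vector(t) for t in toks], axis=0)
        norm = np.linalg.norm(mean)
        if norm == 0.0:  # astronomically unlikely; degenerate cancellation
            raise ValueError("degenerate embedding (zero vector)")
        return mean / norm

    def embed_token(self, token: str) -> np.ndarray:
        """Unit vector for a single normalized token (used by token-level metrics)."""
        vec = self._token_vector(token)
        return vec / np.linalg.norm(vec)


class SentenceEncoderBackend:
    """Adapter for a sentence-transformers encoder behind the same contract.

    Imports lazily; constructing it without the library installed raises
    ImportError.  Uses the encoder's default pooling and unit-normalizes.
    """

    def __init__(self, model_name: str = "all-MiniLM-L6-v2"):
        from sentence_transformers import SentenceTransformer  # noqa: PLC0415

        self._model = SentenceTransformer(model_name)
        self.name = f"sentence-encoder:{model_name}"
        self.dimension = int(self._model.get_sentence_embedding_dimension())
        self.deterministic = True

    def embed(self, text: str) -> np.ndarray:
        if not text.strip():
            raise ValueError("cannot embed empty text")
        vec = np.asarray(self._model.encode([text])[0], dtype=float)
        return vec / np.linalg.norm(vec)

    def embed_token(self, token: str) -> np.ndarray:
        return self.embed(token)


def make_backend(kind: str = "mock", seed: int = 0, model_name: str = "all-MiniLM-L6-v2"):
    """Factory for config keys ``embedding.backend: mock|sentence-encoder``."""
    if kind == "mock":
        return HashEmbeddingBackend(seed=seed)
    if kind == "sentence-encoder":
        return SentenceEncoderBackend(model_name=model_name)
    raise ValueError(f"unknown embedding backend {kind!r}")
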