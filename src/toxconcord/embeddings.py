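"""Term-embedding provider contract and the offline default provider.

The analysis only needs: term -> fixed-length unit vector,
deterministically for a fixed provider version. A live embedding service
can be plugged in by implementing :class:`EmbeddingProvider`; the default
:class:`HashedNgramProvider` derives a reproducible pseudo-vector from
character n-grams (semantics-free, intended for offline tests and
pipeline plumbing).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np


@dataclass
class EmbeddingVector:
    term: str
    values: np.ndarray
    provider_id: str


class EmbeddingProvider(Protocol):
    provider_id: str

    def embed(self, terms: Sequence[str]) -> list[np.ndarray]:
        """Return one equal-length real vector per term."""
        ...


class HashedNgramProvider:
    """Deterministic character-n-gram hashing embedder.

    Each n-gram of the lowercased term is hashed (sha256, keyed by the
    provider seed) to a coordinate and a sign; the accumulated vector is
    L2-normalized. Identical terms therefore share identical vectors
    across runs and platforms, and lexically overlapping terms have
    correlated vectors -- nothing more is claimed.
    """

    def __init__(self, dim: int = 64, n: int = 3, seed: int = 0):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim
        self.n = n
        self.seed = seed
        self.provider_id = f"ngram-hash-v1-d{dim}-n{n}-s{seed}"

    def _grams(self, term: str) -> list[str]:
        t = f"^{term.strip().lower()}$"
        if len(t) <= self.n:
            return [t]
        return [t[i : i + self.n] for i in range(len(t) - self.n + 1)]

    def embed(self, terms: Sequence[str]) -> list[np.ndarray]:
        out = []
        for term in terms:
            v = np.zeros(self.dim)
            for g in self._grams(term):
                h = hashlib.sha256(f"{self.seed}|{g}".encode("utf-8")).digest()
                idx = int.from_bytes(h[:4], "big") % self.dim
                sign = 1.0 if h[4] % 2 == 0 else -1.0
                v[idx] += sign
            norm = np.linalg.norm(v)
            if norm == 0:  # term with no usable characters
                v[0] = 1.0
                norm = 1.0
            out.append(v / norm)
        return out


@dataclass
class EmbeddingCache:
    """In-memory cache keyed by (provider_id, term)."""

    store: dict[tuple[str, str], EmbeddingVector] = field(default_factory=dict)


def embed_terms(
    provider: EmbeddingProvider,
    terms: Sequence[str],
    cache: EmbeddingCache | None = None,
) -> list[EmbeddingVector]:
    """One unit-norm vector per distinct term, cached by (provider, term).

    A provider failure raises with the offending term named; no partial
    silent output is produced.
    """
    cache = cache if cache is not None else EmbeddingCache()
    distinct = list(dict.fromkeys(terms))
    missing = [t for t in distinct if (provider.provider_id, t) not in cache.store]
    if missing:
        try:
            vectors = provider.embed(missing)
        except Exception as exc:  # surface which terms failed
            raise RuntimeError(f"embedding provider failed on terms {missing!r}") from exc
        if len(vectors) != len(missing):
            raise RuntimeError("provider returned a wrong number of vectors")
        for t, v in zip(missing, vectors):
            arr = np.asarray(v, dtype=float)
            norm = np.linalg.norm(arr)
            if norm == 0:
                raise RuntimeError(f"provider returned a zero vector for {t!r}")
            cache.store[(provider.provider_id, t)] = EmbeddingVector(
                term=t, values=arr / norm, provider_id=provider.provider_id
            )
    return [cache.store[(provider.provider_id, t)] for t in distinct]


def cosine_similarity(u: EmbeddingVector, v: EmbeddingVector) -> float:
    """Cosine of two embedding vectors (the dot product for unit vectors)."""
    if u.provider_id != v.provider_id:
        raise ValueError("cosine_similarity requires the same provider")
    if u.values.shape != v.values.shape:
        raise ValueError("dimension mismatch")
    nu, nv = np.linalg.norm(u.values), np.linalg.norm(v.values)
    return float(np.dot(u.values, v.values) / (nu * nv))
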