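"""Term vectors and the cosine ground distance.

Every canonical term must resolve to a fixed (context-free) vector; the
distance between two terms is the cosine distance between their vectors.
Vectors are consumed from any file in word2vec text format, so the
method is decoupled from how the embeddings were trained.

Multi-word terms are composed as the arithmetic mean of their in-vocabulary
token vectors.  A term with no token in the vocabulary falls back to a
deterministic character n-gram (3-6) hash-bucket average, mimicking
subword composition: two runs (or two processes) always produce the same
fallback vector.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmbeddingError

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)
_NGRAM_SALT = b"cohortsim-subword-v1"


@dataclass
class EmbeddingTable:
    """token -> vector map with a fixed dimension; all-zero vectors are not stored."""

    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass(frozen=True)
class TermVector:
    canonical: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(v)):
            raise EmbeddingError(f"non-finite vector for {self.canonical!r}")
        if np.linalg.norm(v) == 0.0:
            raise EmbeddingError(f"zero vector for {self.canonical!r}")
        object.__setattr__(self, "vector", v)


def load_vectors(path: str | Path) -> EmbeddingTable:
    """Load a word2vec text file (header ``N D`` then ``token v1 .. vD`` rows)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty embedding file")
        parts = header.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:1: expected header 'N D', got {header!r}")
        n_declared, dim = int(parts[0]), int(parts[1])
        table = EmbeddingTable(dimension=dim)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(" ")
            if len(fields) != dim + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} floats for token {fields[0]!r}, "
                    f"got {len(fields) - 1}"
                )
            token = fields[0]
            vec = np.asarray([float(x) for x in fields[1:]], dtype=float)
            if not np.any(vec):
                logger.warning("%s:%d: all-zero vector for %r skipped", path, lineno, token)
                continue
            if token in table.vectors:
                logger.warning("%s:%d: duplicate token %r, last occurrence wins", path, lineno, token)
            table.vectors[token] = vec
    if len(table) != n_declared:
        logger.warning(
            "%s: header declares %d rows, stored %d usable vectors", path, n_declared, len(table)
        )
    return table


def save_vectors(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dimension}\n")
        for token in table.vectors:
            row = " ".join(repr(float(x)) for x in table.vectors[token])
            fh.write(f"{token} {row}\n")


def _ngram_bucket_vector(ngram: str, dimension: int) -> np.ndarray:
    digest = hashlib.blake2b(ngram.encode("utf-8"), digest_size=8, salt=_NGRAM_SALT[:8]).digest()
    seed = int.from_bytes(digest, "little") % (2**31)
    rng = np.random.default_rng((seed, dimension))
    return rng.standard_normal(dimension)


def _subword_vector(token: str, dimension: int) -> np.ndarray:
    padded = f"<{token}>"
    grams = [padded[i : i + n] for n in range(3, 7) for i in range(len(padded) - n + 1)]
    if not grams:
        grams = [padded]
    return np.mean([_ngram_bucket_vector(g, dimension) for g in grams], axis=0)


def embed_term(canonical: str, table: EmbeddingTable) -> TermVector:
    """Vector of a canonical term.

    Single in-vocabulary token: its stored vector.  Multi-token: mean of
    the in-vocabulary token vectors.  Fully out of vocabulary: the
    deterministic subword fallback.
    """
    tokens = _TOKEN_RE.findall(canonical)
    if not tokens:
        raise EmbeddingError(f"term {canonical!r} contains no word token")
    in_vocab = []
    for tok in tokens:
        if tok in table.vectors:
            in_vocab.append(table.vectors[tok])
        elif tok.casefold() in table.vectors:
            in_vocab.append(table.vectors[tok.casefold()])
    if in_vocab:
        vec = np.mean(in_vocab, axis=0)
    else:
        vec = np.mean([_subword_vector(tok.casefold(), table.dimension) for tok in tokens], axis=0)
    if np.linalg.norm(vec) == 0.0:
        raise EmbeddingError(f"term {canonical!r} resolved to a zero vector")
    return TermVector(canonical=canonical, vector=vec)


def cosine_distance(u: TermVector | np.ndarray, v: TermVector | np.ndarray) -> float:
    """1 - cos(u, v), clamped to [0, 2] against rounding."""
    uv = u.vector if isinstance(u, TermVector) else np.asarray(u, dtype=float)
    vv = v.vector if isinstance(v, TermVector) else np.asarray(v, dtype=float)
    nu = np.linalg.norm(uv)
    nv = np.linalg.norm(vv)
    if nu == 0.0 or nv == 0.0:
        raise EmbeddingError("cosine distance undefined for zero-norm vector")
    return float(np.clip(1.0 - float(uv @ vv) / (nu * nv), 0.0, 2.0))
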