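"""Semantic geometry: item embeddings and pairwise cosine similarities.

Items live on the unit sphere; cosine similarity therefore equals the dot
product.  A synthetic generator with a single clusterability knob stands in
for pretrained word embeddings so that every analysis can run offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SemanticSpace",
    "generate_synthetic_space",
    "cosine",
    "load_embeddings",
    "save_embeddings",
    "load_wordlist",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class SemanticSpace:
    """Ordered items with unit embedding vectors and their Gram matrix.

    Attributes
    ----------
    items : tuple of str
        Item labels in canonical order.
    vectors : ndarray of shape (n, d)
        Unit-norm embedding per item.
    similarity : ndarray of shape (n, n)
        Pairwise cosines; symmetric, unit diagonal, entries in [-1, 1].
    """

    items: tuple
    vectors: np.ndarray
    similarity: np.ndarray = field(default=None)

    def __post_init__(self):
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.ndim != 2 or len(self.items) != vectors.shape[0]:
            raise ValueError("vectors must be (n_items, dim)")
        norms = np.linalg.norm(vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("embedding vectors must have unit norm")
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "vectors", vectors)
        if self.similarity is None:
            object.__setattr__(self, "similarity", _gram(vectors))
        else:
            sim = np.asarray(self.similarity, dtype=float)
            if sim.shape != (len(self.items),) * 2:
                raise ValueError("similarity must be n x n")
            object.__setattr__(self, "similarity", sim)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def _gram(vectors: np.ndarray) -> np.ndarray:
    sim = vectors @ vectors.T
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def generate_synthetic_space(
    n_items: int,
    dim: int,
    n_clusters: int | None = None,
    cluster_spread: float = 0.1,
    seed: int | None = None,
) -> SemanticSpace:
    """Generate a clusterable synthetic semantic space.

    Draws ``n_clusters`` centroid directions uniformly on the sphere and
    places each item at ``normalize(centroid + cluster_spread * noise)``.
    ``n_clusters == n_items`` (the default) yields an unstructured space of
    independent random directions.  Deterministic given ``seed``.

    Parameters
    ----------
    n_items : int
        Number of items (>= 2).
    dim : int
        Embedding dimension (>= 2).
    n_clusters : int, optional
        Number of semantic clusters; defaults to ``n_items`` (no structure).
    cluster_spread : float
        Isotropic noise scale around each centroid; small values give tight
        clusters, large values approach an unstructured space.
    seed : int, optional
        RNG seed.
    """
    if n_clusters is None:
        n_clusters = n_items
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if not 1 <= n_clusters <= n_items:
        raise ValueError("n_clusters must be in [1, n_items]")
    if cluster_spread < 0:
        raise ValueError("cluster_spread must be nonnegative")
    rng = np.random.default_rng(seed)
    centroids = rng.standard_normal((n_clusters, dim))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    assignments = np.arange(n_items) % n_clusters
    noise = rng.standard_normal((n_items, dim))
    vectors = centroids[assignments] + cluster_spread * noise
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    width = max(3, len(str(n_items)))
    items = tuple(f"w{i + 1:0{width}d}" for i in range(n_items))
    return SemanticSpace(items=items, vectors=vectors)


def cluster_labels(n_items: int, n_clusters: int) -> np.ndarray:
    """Cluster assignment used by :func:`generate_synthetic_space`."""
    return np.arange(n_items) % n_clusters


def cosine(space: SemanticSpace, i: int, j: int) -> float:
    """Pairwise cosine similarity between items ``i`` and ``j``."""
    n = space.n_items
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"item index out of range for space of size {n}")
    return float(space.similarity[i, j])


def load_wordlist(path) -> list:
    """Read a UTF-8 word list, one item per line, blank lines skipped."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def load_embeddings(path, wordlist=None) -> SemanticSpace:
    """Load a word2vec-text embedding file restricted to ``wordlist``.

    The file starts with a header line ``"n d"`` followed by ``word v1 ... vd``
    rows.  Vectors are re-normalized to unit length; item order follows
    ``wordlist`` (or the file order when ``wordlist`` is None).  A word absent
    from the file raises ``KeyError`` naming it; malformed lines raise
    ``ValueError`` with the line number.
    """
    table = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        parts = header.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: line 1: malformed word2vec header {header!r}")
        try:
            n_decl, dim = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}: line 1: malformed word2vec header {header!r}") from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != dim + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {dim + 1} fields, got {len(fields)}"
                )
            try:
                vec = np.array([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric vector entry") from exc
            table[fields[0]] = vec
    wordlist = list(table) if wordlist is None else list(wordlist)
    missing = [w for w in wordlist if w not in table]
    if missing:
        raise KeyError(f"word(s) not found in embeddings: {', '.join(missing)}")
    vectors = np.stack([_unit(table[w]) for w in wordlist])
    return SemanticSpace(items=tuple(wordlist), vectors=vectors)


def save_embeddings(space: SemanticSpace, path) -> None:
    """Write a space in word2vec text format (round-trips with the loader)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{space.n_items} {space.dim}\n")
        for word, vec in zip(space.items, space.vectors):
            coords = " ".join(repr(float(x)) for x in vec)
            fh.write(f"{word} {coords}\n")
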