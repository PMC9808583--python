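"""Agglomerative Ward clustering over precomputed patient distances.

Each document starts as a singleton cluster and clusters are merged
two-by-two under Ward's minimum-variance criterion, applied to the
earth-mover's dissimilarity matrix through the Lance-Williams recurrence
(as SciPy does).  Ward formally presumes Euclidean distances and EMD
values are not Euclidean; clustering them anyway is a deliberate,
documented choice — the dissimilarity is treated as-if-Euclidean, which
is standard practice for this kind of matrix.  Merge heights are checked
for monotonicity and violations are reported, not hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage, to_tree
from scipy.spatial.distance import squareform

from .patient import PatientRepresentation
from .similarity import DistanceMatrix, label_distance

logger = logging.getLogger(__name__)


@dataclass
class Linkage:
    """A linkage tree: scipy (n-1, 4) merge matrix plus leaf document ids."""

    Z: np.ndarray
    ids: tuple[str, ...]

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [(int(a), int(b), float(h), int(s)) for a, b, h, s in self.Z]

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2].copy()

    def to_csv(self, path: str | Path, float_format: str = "%.9f") -> None:
        df = pd.DataFrame(self.Z, columns=["cluster_a", "cluster_b", "height", "size"])
        df.to_csv(path, index=False, float_format=float_format)

    def to_newick(self, path: str | Path | None = None) -> str:
        """Dendrogram as a Newick string (branch length = height difference)."""
        root = to_tree(self.Z)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.9f}"
            return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.9f}"

        text = f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _validate_square(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError(
            "distance matrix contains incomparable (NA) pairs; impute or drop them first"
        )
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return (D + D.T) / 2.0


def ward_linkage(D: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None) -> Linkage:
    """Ward linkage of a precomputed dissimilarity matrix."""
    if isinstance(D, DistanceMatrix):
        ids = D.ids
        D = D.values
    values = _validate_square(D)
    if ids is None:
        ids = tuple(str(i) for i in range(values.shape[0]))
    Z = scipy_linkage(squareform(values, checks=False), method="ward")
    heights = Z[:, 2]
    if np.any(np.diff(heights) < -1e-9):
        logger.warning("non-monotone merge heights (dissimilarity is not Euclidean)")
    return Linkage(Z=Z, ids=tuple(str(i) for i in ids))


def cut(linkage: Linkage, k: int) -> dict[str, int]:
    """Flat partition into exactly k clusters: document id -> cluster index."""
    n = len(linkage.ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    assignment = cut_tree(linkage.Z, n_clusters=k).ravel()
    return {doc: int(c) for doc, c in zip(linkage.ids, assignment)}


def label_restricted_clustering(
    reps: Sequence[PatientRepresentation], label: str, cache=None
) -> Linkage:
    """Ward linkage of the documents carrying one label, under that label's EMD."""
    carriers = [r for r in reps if label in r.per_label]
    if len(carriers) < 2:
        raise ValueError(f"label {label!r} has {len(carriers)} carrier(s); need at least 2")
    n = len(carriers)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = label_distance(carriers[i], carriers[j], label, cache=cache)
    return ward_linkage(D, ids=[r.document_id for r in carriers])
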