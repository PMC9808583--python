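"""Label-wise earth mover's distance and the global patient distance.

Two documents are compared label by label.  On one label, each document
is a weighted cloud of term vectors (mass = normalized occurrence
frequency) and the distance is the earth mover's distance with cosine
ground costs, solved exactly.  Globally,

    D(HR1, HR2) = (1/n_labels) * sum_i  lambda_i * EMD_i

with per-label weight

    lambda_i = (n_HR1(label_i) + n_HR2(label_i)) / (n_HR1 + n_HR2),

where n_HR(label_i) is the number of term occurrences a report carries
on the label and n_HR its total term count.  Labels with many terms on
either side therefore dominate the sum.

Which labels enter the sum is configurable: ``intersection`` (default)
includes only labels present in both reports, matching the per-label
precondition that each record carries at least one term for the label;
``penalty`` additionally includes one-sided labels at a fixed EMD
penalty.  ``n_labels`` counts the labels actually included, so sparse
documents are not shrunk toward zero by empty labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, MutableMapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyRepresentationError,
    IncomparableRepresentationsError,
    TransportError,
)
from .patient import LabelDistribution, PatientRepresentation
from .transport import solve_transport

logger = logging.getLogger(__name__)

#: cache type: (label, doc_id_a, doc_id_b) -> per-label EMD, ids sorted
EMDCache = MutableMapping[tuple[str, str, str], float]


@dataclass(frozen=True)
class GlobalDistanceConfig:
    """Options of the global distance.

    label_subset restricts the label universe first (phenotype routing);
    missing_label_mode decides what happens to labels carried by only
    one of the two reports.
    """

    label_subset: frozenset[str] | None = None
    missing_label_mode: str = "intersection"
    penalty_value: float = 1.0

    def __post_init__(self) -> None:
        if self.missing_label_mode not in ("intersection", "penalty"):
            raise ValueError(f"unknown missing_label_mode {self.missing_label_mode!r}")
        if not (0.0 <= self.penalty_value <= 2.0):
            raise ValueError("penalty_value must lie in [0, 2]")
        if self.label_subset is not None:
            object.__setattr__(self, "label_subset", frozenset(self.label_subset))

    def restricted(self, labels: Iterable[str] | None) -> "GlobalDistanceConfig":
        if labels is None:
            return self
        return replace(self, label_subset=frozenset(labels))


def _cost_matrix(a: LabelDistribution, b: LabelDistribution) -> np.ndarray:
    ua = np.stack([p.vector for p in a.points])
    ub = np.stack([p.vector for p in b.points])
    ua = ua / np.linalg.norm(ua, axis=1, keepdims=True)
    ub = ub / np.linalg.norm(ub, axis=1, keepdims=True)
    return np.clip(1.0 - ua @ ub.T, 0.0, 2.0)


def emd(a: LabelDistribution, b: LabelDistribution) -> float:
    """Exact earth mover's distance between two label distributions."""
    cost = _cost_matrix(a, b)
    try:
        value, _ = solve_transport(cost, a.weights, b.weights)
    except TransportError:  # pragma: no cover - degenerate cycling guard
        logger.warning("transportation simplex stalled; falling back to generic LP")
        from scipy.optimize import linprog

        m, n = cost.shape
        A_eq = np.zeros((m + n, m * n))
        for i in range(m):
            A_eq[i, i * n : (i + 1) * n] = 1.0
        for j in range(n):
            A_eq[m + j, j::n] = 1.0
        res = linprog(
            cost.ravel(),
            A_eq=A_eq,
            b_eq=np.concatenate([a.weights, b.weights]),
            bounds=(0, None),
            method="highs",
        )
        if res.status != 0:
            raise TransportError(f"LP fallback failed: {res.message}")
        value = float(res.fun)
    return max(value, 0.0)


def lambda_weight(n1_i: int, n2_i: int, n1: int, n2: int) -> float:
    """Per-label weight (n1_i + n2_i) / (n1 + n2)."""
    if n1_i < 0 or n2_i < 0 or n1 < 0 or n2 < 0:
        raise ValueError("term counts must be non-negative")
    if n1 + n2 == 0:
        raise EmptyRepresentationError("two empty reports are incomparable")
    return (n1_i + n2_i) / (n1 + n2)


def label_distance(
    r1: PatientRepresentation,
    r2: PatientRepresentation,
    label: str,
    cache: EMDCache | None = None,
) -> float:
    """EMD between two documents on one label; both sides must carry it."""
    for side, rep in (("first", r1), ("second", r2)):
        if label not in rep.per_label:
            raise IncomparableRepresentationsError(
                f"label {label!r} absent from the {side} representation ({rep.document_id})"
            )
    if cache is not None:
        key = (label, *sorted((r1.document_id, r2.document_id)))
        if key in cache:
            return cache[key]
    value = emd(r1.distribution(label), r2.distribution(label))
    if cache is not None:
        cache[key] = value
    return value


def _universe(rep: PatientRepresentation, cfg: GlobalDistanceConfig) -> frozenset[str]:
    labels = rep.labels
    if cfg.label_subset is not None:
        labels &= cfg.label_subset
    return labels


def global_distance(
    r1: PatientRepresentation,
    r2: PatientRepresentation,
    cfg: GlobalDistanceConfig | None = None,
    cache: EMDCache | None = None,
) -> float:
    """Label-weighted mean of per-label earth mover's distances."""
    cfg = cfg or GlobalDistanceConfig()
    l1, l2 = _universe(r1, cfg), _universe(r2, cfg)
    if not l1 or not l2:
        raise EmptyRepresentationError(
            f"representation {'/'.join(r.document_id for r in (r1, r2) if not _universe(r, cfg))} "
            "carries no labeled term within the configured label universe"
        )
    if cfg.missing_label_mode == "intersection":
        included = l1 & l2
        if not included:
            raise IncomparableRepresentationsError(
                f"documents {r1.document_id} and {r2.document_id} share no label"
            )
    else:
        included = l1 | l2

    n1, n2 = r1.total_terms, r2.total_terms
    total = 0.0
    for label in sorted(included):
        lam = lambda_weight(r1.n_terms(label), r2.n_terms(label), n1, n2)
        if label in l1 and label in l2:
            d = label_distance(r1, r2, label, cache=cache)
        else:
            d = cfg.penalty_value
        total += lam * d
    return total / len(included)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with NaN marking incomparable pairs."""

    ids: tuple[str, ...]
    values: np.ndarray
    incomparable: list[tuple[str, str]] = field(default_factory=list)

    def to_csv(self, path: str | Path, float_format: str = "%.9f") -> None:
        df = pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))
        df.to_csv(path, na_rep="NA", float_format=float_format)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        values = df.to_numpy(dtype=float)
        ids = tuple(str(i) for i in df.index)
        incomparable = [
            (ids[i], ids[j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if np.isnan(values[i, j])
        ]
        return cls(ids=ids, values=values, incomparable=incomparable)


def distance_matrix(
    reps: Sequence[PatientRepresentation],
    cfg: GlobalDistanceConfig | None = None,
    cache: EMDCache | None = None,
) -> DistanceMatrix:
    """All-pairs global distances; incomparable pairs become NaN and are reported."""
    if len(reps) < 2:
        raise ValueError("need at least 2 representations")
    cfg = cfg or GlobalDistanceConfig()
    if cache is None:
        cache = {}
    n = len(reps)
    values = np.zeros((n, n))
    incomparable: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = global_distance(reps[i], reps[j], cfg, cache=cache)
            except (IncomparableRepresentationsError, EmptyRepresentationError):
                d = np.nan
                incomparable.append((reps[i].document_id, reps[j].document_id))
            values[i, j] = values[j, i] = d
    if incomparable:
        logger.info("%d of %d pairs are incomparable", len(incomparable), n * (n - 1) // 2)
    return DistanceMatrix(
        ids=tuple(r.document_id for r in reps), values=values, incomparable=incomparable
    )
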