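"""Ranked cohort retrieval from an index patient, with IR metrics.

Cohort construction is framed as information retrieval: the index
patient's document is the query, every other patient's documents are the
collection, and the phenotype-routed global distance ranks them.  Only
the closest document of each distinct patient is kept.  Evaluation
rotates every gold-positive document as the index patient and averages
precision@k, recall at n (n = number of gold-positive patients) and
average precision over the rotations, with normal-approximation 95%
confidence intervals.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptyRepresentationError, IncomparableRepresentationsError
from .patient import PatientRepresentation
from .similarity import EMDCache, GlobalDistanceConfig, global_distance

logger = logging.getLogger(__name__)


def read_routing_tsv(path: str | Path) -> dict[str, frozenset[str]]:
    """Read ``phenotype<TAB>comma-separated-labels`` routing rows."""
    routing: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed routing row: {line!r}")
            routing[parts[0].strip()] = frozenset(
                l.strip() for l in parts[1].split(",") if l.strip()
            )
    return routing


def default_routing() -> dict[str, frozenset[str]]:
    from .resources import default_phenotype_routing

    return default_phenotype_routing()


def read_gold_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read ``document_id<TAB>phenotype`` rows (several rows per document allowed)."""
    gold: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed gold row: {line!r}")
            gold.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return gold


@dataclass(frozen=True)
class CohortEntry:
    patient_id: str
    document_id: str
    distance: float


@dataclass
class RankedCohort:
    """Distance-ordered list of distinct patients retrieved for one index document."""

    index_document_id: str
    entries: list[CohortEntry]
    relevance: list[int] | None = None
    n_incomparable: int = 0

    def __post_init__(self) -> None:
        dists = [e.distance for e in self.entries]
        if any(b < a - 1e-12 for a, b in zip(dists, dists[1:])):
            raise ValueError("entries must be sorted by non-decreasing distance")
        if self.relevance is not None and len(self.relevance) != len(self.entries):
            raise ValueError("relevance flags must align with entries")

    def with_relevance(self, positive_patients: Iterable[str]) -> "RankedCohort":
        positives = set(positive_patients)
        return replace(
            self, relevance=[int(e.patient_id in positives) for e in self.entries]
        )


def rank_cohort(
    index: PatientRepresentation,
    candidates: Sequence[PatientRepresentation],
    labels: Iterable[str] | None = None,
    cfg: GlobalDistanceConfig | None = None,
    cache: EMDCache | None = None,
) -> RankedCohort:
    """Rank candidate documents by routed distance to the index document.

    Documents of the index patient must not be among the candidates.
    For each distinct patient only the minimum-distance document is kept;
    ties are broken by document id.  Candidates incomparable to the index
    (no shared label) are dropped and counted.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    for c in candidates:
        if c.document_id == index.document_id or c.patient_id == index.patient_id:
            raise ValueError(
                f"candidate {c.document_id} belongs to the index patient; exclude it"
            )
    cfg = (cfg or GlobalDistanceConfig()).restricted(labels)
    best: dict[str, CohortEntry] = {}
    n_incomparable = 0
    for cand in candidates:
        try:
            d = global_distance(index, cand, cfg, cache=cache)
        except (IncomparableRepresentationsError, EmptyRepresentationError):
            n_incomparable += 1
            continue
        prev = best.get(cand.patient_id)
        if (
            prev is None
            or d < prev.distance
            or (d == prev.distance and cand.document_id < prev.document_id)
        ):
            best[cand.patient_id] = CohortEntry(cand.patient_id, cand.document_id, d)
    if not best:
        raise IncomparableRepresentationsError(
            f"no candidate is comparable to index document {index.document_id}"
        )
    entries = sorted(best.values(), key=lambda e: (e.distance, e.document_id))
    return RankedCohort(
        index_document_id=index.document_id, entries=entries, n_incomparable=n_incomparable
    )


# ---------------------------------------------------------------------------
# ranked-retrieval metrics
# ---------------------------------------------------------------------------


def _require_relevance(cohort: RankedCohort) -> list[int]:
    if cohort.relevance is None:
        raise ValueError("cohort carries no relevance flags; call with_relevance first")
    return cohort.relevance


def precision_at_k(cohort: RankedCohort, k: int) -> float:
    """Fraction of relevant patients among the first k retrieved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    flags = _require_relevance(cohort)
    if len(flags) < k:
        logger.warning(
            "only %d retrievable patients for k=%d; missing ranks count as irrelevant",
            len(flags),
            k,
        )
    return sum(flags[:k]) / k


def recall_at_n(
    cohort: RankedCohort, n: int | None = None, total_relevant: int | None = None
) -> float:
    """Fraction of all relevant patients found in the first n ranks.

    By default n equals the number of relevant patients in the pool (the
    phenotype's cohort size) and the denominator counts every relevant
    patient in the candidate pool.
    """
    flags = _require_relevance(cohort)
    if total_relevant is None:
        total_relevant = sum(flags)
    if total_relevant == 0:
        raise ValueError("no relevant patient in the pool; recall undefined")
    if n is None:
        n = total_relevant
    if n < 1:
        raise ValueError("n must be >= 1")
    return sum(flags[:n]) / total_relevant


def average_precision(cohort: RankedCohort, total_relevant: int | None = None) -> float:
    """Mean of precision@r over the ranks r of relevant hits (PR-curve area estimate)."""
    flags = _require_relevance(cohort)
    if total_relevant is None:
        total_relevant = sum(flags)
    if total_relevant == 0:
        raise ValueError("no relevant patient in the pool; average precision undefined")
    hits = 0
    acc = 0.0
    for rank, flag in enumerate(flags, start=1):
        if flag:
            hits += 1
            acc += hits / rank
    return acc / total_relevant


# ---------------------------------------------------------------------------
# phenotype evaluation with index-patient rotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "MetricSummary":
        v = np.asarray(values, dtype=float)
        mean = float(v.mean())
        if len(v) > 1:
            half = 1.96 * float(v.std(ddof=1)) / math.sqrt(len(v))
        else:
            half = 0.0
        return cls(mean=mean, ci_low=max(mean - half, 0.0), ci_high=min(mean + half, 1.0))


@dataclass
class PhenotypeEvaluation:
    """Rotation-averaged retrieval metrics for one phenotype."""

    phenotype: str
    labels: frozenset[str]
    n_index: int
    n_relevant_patients: int
    metrics: dict[str, MetricSummary]
    per_index: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "labels": sorted(self.labels),
            "n_index": self.n_index,
            "n_relevant_patients": self.n_relevant_patients,
            "metrics": {
                name: {
                    "mean": round(s.mean, 9),
                    "ci_low": round(s.ci_low, 9),
                    "ci_high": round(s.ci_high, 9),
                }
                for name, s in self.metrics.items()
            },
        }


def evaluate_phenotype(
    reps: Sequence[PatientRepresentation],
    gold: Mapping[str, set[str]],
    phenotype: str,
    routing: Mapping[str, frozenset[str]] | None = None,
    cfg: GlobalDistanceConfig | None = None,
    ks: Sequence[int] = (3, 10),
    cache: EMDCache | None = None,
) -> PhenotypeEvaluation:
    """Rotate every gold-positive document as index patient and average the metrics.

    A patient is relevant when any of their documents carries the
    phenotype annotation.  The index patient (all their documents) is
    excluded from the candidate pool of their own rotation.
    """
    routing = routing if routing is not None else default_routing()
    if phenotype not in routing:
        raise KeyError(f"no label routing for phenotype {phenotype!r}")
    labels = routing[phenotype]
    positive_docs = [r for r in reps if phenotype in gold.get(r.document_id, set())]
    positive_patients = {r.patient_id for r in positive_docs}
    if len(positive_patients) < 2:
        raise ValueError(
            f"phenotype {phenotype!r} has {len(positive_patients)} positive patient(s); "
            "need at least 2 for index rotation"
        )
    if cache is None:
        cache = {}
    per_index: dict[str, list[float]] = {
        **{f"precision_at_{k}": [] for k in ks},
        "average_precision": [],
        "recall": [],
    }
    for index in positive_docs:
        candidates = [r for r in reps if r.patient_id != index.patient_id]
        pool_relevant = len(positive_patients - {index.patient_id})
        cohort = rank_cohort(index, candidates, labels=labels, cfg=cfg, cache=cache)
        cohort = cohort.with_relevance(positive_patients)
        for k in ks:
            per_index[f"precision_at_{k}"].append(precision_at_k(cohort, k))
        per_index["average_precision"].append(
            average_precision(cohort, total_relevant=pool_relevant)
        )
        per_index["recall"].append(recall_at_n(cohort, total_relevant=pool_relevant))
    return PhenotypeEvaluation(
        phenotype=phenotype,
        labels=frozenset(labels),
        n_index=len(positive_docs),
        n_relevant_patients=len(positive_patients),
        metrics={name: MetricSummary.from_values(vals) for name, vals in per_index.items()},
        per_index=per_index,
    )


def evaluate_phenotypes(
    reps: Sequence[PatientRepresentation],
    gold: Mapping[str, set[str]],
    phenotypes: Iterable[str] | None = None,
    routing: Mapping[str, frozenset[str]] | None = None,
    cfg: GlobalDistanceConfig | None = None,
    ks: Sequence[int] = (3, 10),
) -> dict[str, PhenotypeEvaluation]:
    """Evaluate several phenotypes, sharing one per-label EMD cache."""
    routing = routing if routing is not None else default_routing()
    if phenotypes is None:
        phenotypes = sorted({p for phenos in gold.values() for p in phenos} & set(routing))
    cache: EMDCache = {}
    return {
        p: evaluate_phenotype(reps, gold, p, routing=routing, cfg=cfg, ks=ks, cache=cache)
        for p in phenotypes
    }


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_metric_report(
    evaluations: Mapping[str, PhenotypeEvaluation], path: str | Path
) -> None:
    payload = {name: ev.to_dict() for name, ev in sorted(evaluations.items())}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def format_ranked_table(cohort: RankedCohort, limit: int | None = 20) -> str:
    """Human-readable ranked table (plain-text replacement for a search UI)."""
    lines = [
        f"index document: {cohort.index_document_id}"
        + (f"  (incomparable candidates dropped: {cohort.n_incomparable})" if cohort.n_incomparable else ""),
        f"{'rank':>4}  {'patient':<12} {'document':<12} {'distance':>10}  relevant",
    ]
    entries = cohort.entries if limit is None else cohort.entries[:limit]
    for rank, e in enumerate(entries, start=1):
        rel = ""
        if cohort.relevance is not None:
            rel = "yes" if cohort.relevance[rank - 1] else "no"
        lines.append(
            f"{rank:>4}  {e.patient_id:<12} {e.document_id:<12} {e.distance:>10.6f}  {rel}"
        )
    return "\n".join(lines) + "\n"
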