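"""Per-document patient representations.

A hospitalization report is represented as a map ``label -> weighted
term distribution``: for each organ-system label, the terms the report
carries under that label, with masses proportional to their occurrence
counts and a vector attached to each term.  This object is what both the
per-label earth mover's distance and the global weighted distance
consume.

A multilabel term (e.g. systemic lupus erythematosus -> immune *and*
skin) appears under every one of its labels, but ``total_terms`` counts
each occurrence once: it is the per-document term count n_HR entering
the label weight denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .embeddings import EmbeddingTable, TermVector, embed_term
from .errors import EmbeddingError
from .labels import LabeledTerm
from .text import ClinicalNote


@dataclass(frozen=True)
class LabelDistribution:
    """A weighted point cloud of term vectors (weights sum to 1)."""

    points: tuple[TermVector, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.points) != len(w) or len(w) < 1:
            raise ValueError("points and weights must be non-empty and aligned")
        if np.any(w < 0) or abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)


@dataclass
class PatientRepresentation:
    """One document's per-label weighted term distributions."""

    document_id: str
    patient_id: str
    per_label: dict[str, list[tuple[TermVector, int]]] = field(default_factory=dict)
    total_terms: int = 0

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.per_label)

    def n_terms(self, label: str) -> int:
        """Occurrence count carried by one label (0 when absent)."""
        return sum(count for _, count in self.per_label.get(label, []))

    def distribution(self, label: str) -> LabelDistribution:
        return to_distribution(self.per_label[label])


def to_distribution(entries: Sequence[tuple[TermVector, int]]) -> LabelDistribution:
    """Normalize occurrence counts into masses, preserving point order."""
    if not entries:
        raise ValueError("cannot build a distribution from an empty entry list")
    counts = np.asarray([count for _, count in entries], dtype=float)
    return LabelDistribution(
        points=tuple(tv for tv, _ in entries), weights=counts / counts.sum()
    )


def build_representation(
    note: ClinicalNote | tuple[str, str],
    labeled_terms: Iterable[LabeledTerm],
    table: EmbeddingTable,
) -> PatientRepresentation:
    """Assemble the per-label representation of one document.

    Each labeled term appears under every one of its labels with its
    count; ``total_terms`` sums counts over distinct terms (each term
    once, however many labels it carries).
    """
    if isinstance(note, ClinicalNote):
        document_id, patient_id = note.document_id, note.patient_id
    else:
        document_id, patient_id = note
    rep = PatientRepresentation(document_id=document_id, patient_id=patient_id)
    for term in labeled_terms:
        try:
            tv = embed_term(term.canonical, table)
        except EmbeddingError as exc:
            raise EmbeddingError(f"document {document_id}: {exc}") from exc
        for label in sorted(term.labels):
            rep.per_label.setdefault(label, []).append((tv, term.count))
        rep.total_terms += term.count
    return rep


# ---------------------------------------------------------------------------
# serialization (vectors are re-resolved from the embedding table at load)
# ---------------------------------------------------------------------------


def write_representations_jsonl(
    reps: Iterable[PatientRepresentation], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rep in reps:
            obj = {
                "document_id": rep.document_id,
                "patient_id": rep.patient_id,
                "total_terms": rep.total_terms,
                "per_label": {
                    label: [[tv.canonical, count] for tv, count in entries]
                    for label, entries in sorted(rep.per_label.items())
                },
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_representations_jsonl(
    path: str | Path, table: EmbeddingTable
) -> list[PatientRepresentation]:
    reps = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            rep = PatientRepresentation(
                document_id=obj["document_id"],
                patient_id=obj["patient_id"],
                total_terms=int(obj["total_terms"]),
            )
            for label, entries in obj["per_label"].items():
                rep.per_label[label] = [
                    (embed_term(canonical, table), int(count)) for canonical, count in entries
                ]
            reps.append(rep)
    return reps
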