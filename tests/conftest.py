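from __future__ import annotations

import numpy as np
import pytest

from cohortsim.embeddings import EmbeddingTable, TermVector
from cohortsim.labels import LabelScheme
from cohortsim.patient import LabelDistribution, PatientRepresentation
from cohortsim.text import ClinicalNote, CueLexicon


def make_table(tokens: list[str], dimension: int = 6, seed: int = 0) -> EmbeddingTable:
    rng = np.random.default_rng(seed)
    table = EmbeddingTable(dimension=dimension)
    for tok in tokens:
        table.vectors[tok] = rng.standard_normal(dimension)
    return table


def random_distribution(rng: np.random.Generator, n_points: int, dim: int = 6) -> LabelDistribution:
    points = tuple(
        TermVector(f"t{i}", rng.standard_normal(dim)) for i in range(n_points)
    )
    counts = rng.integers(1, 5, size=n_points).astype(float)
    return LabelDistribution(points=points, weights=counts / counts.sum())


def random_representation(
    rng: np.random.Generator,
    doc_id: str,
    labels: list[str],
    multilabel: bool = False,
    dim: int = 6,
) -> PatientRepresentation:
    """A representation with 1-3 terms per label, single- or multi-labeled."""
    rep = PatientRepresentation(document_id=doc_id, patient_id=f"p_{doc_id}")
    term_idx = 0
    for label in labels:
        for _ in range(int(rng.integers(1, 4))):
            tv = TermVector(f"{doc_id}_t{term_idx}", rng.standard_normal(dim))
            count = int(rng.integers(1, 4))
            rep.per_label.setdefault(label, []).append((tv, count))
            if multilabel and rng.random() < 0.5 and len(labels) > 1:
                other = labels[int(rng.integers(len(labels)))]
                if other != label:
                    rep.per_label.setdefault(other, []).append((tv, count))
            rep.total_terms += count
            term_idx += 1
    return rep


@pytest.fixture
def index_patient_fixture():
    """Hand-built micro-corpus mirroring a lupus index patient.

    The note carries four immune-label findings (systemic lupus
    erythematosus, lupus pericarditis, Raynaud, Gougerot-Sjogren), one
    nervous finding, one hematoma, and one hypothetical angioedema that
    assertion filtering must exclude.
    """
    note = ClinicalNote(
        document_id="index_patient",
        patient_id="index_patient",
        text=(
            "Suspicion d'angioedème. "
            "Lupus érythémateux disséminé connu avec péricardite lupique, "
            "syndrome de Raynaud et Gougerot-Sjögren. "
            "État de mal épileptique focal pariétal. Hématome fronto-pariétal."
        ),
    )
    concept_lexicon = {
        "lupus erythemateux dissemine": "systemic lupus erythematosus",
        "pericardite lupique": "lupus pericarditis",
        "syndrome de raynaud": "raynaud syndrome",
        "gougerot-sjogren": "gougerot-sjogren",
        "etat de mal epileptique focal parietal": "parietal focal status epilepticus",
        "hematome fronto-parietal": "frontoparietal hematoma",
        "angioedeme": "angioedema",
    }
    label_lexicon = {
        "systemic lupus erythematosus": frozenset({"immune", "skin"}),
        "lupus pericarditis": frozenset({"immune", "cardiovascular"}),
        "raynaud syndrome": frozenset({"immune"}),
        "gougerot-sjogren": frozenset({"immune"}),
        "parietal focal status epilepticus": frozenset({"nervous"}),
        "frontoparietal hematoma": frozenset({"nervous"}),
        "angioedema": frozenset({"immune", "skin"}),
    }
    cues = CueLexicon(
        negation_cues=("pas de", "sans"),
        hypothesis_cues=("suspicion de", "suspicion d'"),
        family_cues=("antécédents familiaux de",),
        scope_window=5,
    )
    tokens = sorted({tok for canon in label_lexicon for tok in canon.replace("-", " ").split()})
    table = make_table(tokens, dimension=8, seed=42)
    scheme = LabelScheme.default()
    return note, concept_lexicon, label_lexicon, cues, table, scheme
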