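"""scikit-learn-style estimators over the pipeline stages.

The pipeline's batch stages are fit/transform-shaped, so they are
exposed as estimators that compose with sklearn tooling:

* :class:`CohortVectorizer` — notes -> per-label patient representations;
* :class:`EMDPairwiseDistance` — representations -> pairwise distance matrix
  (``metric='precomputed'`` consumers can sit downstream);
* :class:`WardCohortClustering` — precomputed distances -> flat clusters;
* :class:`CohortRetriever` — fit a candidate pool, query index patients.

Parameters follow sklearn conventions (settable in ``__init__``, fitted
attributes with a trailing underscore, ``get_params``/``set_params``
inherited from :class:`~sklearn.base.BaseEstimator`).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cluster import Linkage, cut, ward_linkage
from .embeddings import EmbeddingTable
from .labels import LabelScheme
from .patient import PatientRepresentation
from .pipeline import notes_to_representations
from .retrieval import RankedCohort, rank_cohort
from .similarity import EMDCache, GlobalDistanceConfig, global_distance
from .text import ClinicalNote, CueLexicon


def _as_notes(X: Iterable) -> list[ClinicalNote]:
    notes = []
    for item in X:
        if isinstance(item, ClinicalNote):
            notes.append(item)
        elif isinstance(item, Mapping):
            notes.append(ClinicalNote(str(item["document_id"]), str(item["patient_id"]), item["text"]))
        else:
            raise TypeError(f"cannot interpret {type(item).__name__} as a clinical note")
    return notes


class CohortVectorizer(TransformerMixin, BaseEstimator):
    """Turn raw notes into per-label weighted term-vector representations.

    Parameters
    ----------
    concept_lexicon : mapping surface -> canonical term
    label_lexicon : mapping canonical term -> set of labels
    cues : CueLexicon or None
        Assertion trigger phrases; the shipped default when None.
    table : EmbeddingTable
        Term vectors (word2vec text format loadable via
        :func:`cohortsim.embeddings.load_vectors`).
    scheme : LabelScheme or None
        Label universe; the shipped 22-chapter scheme when None.
    """

    def __init__(
        self,
        concept_lexicon: Mapping[str, str] | None = None,
        label_lexicon: Mapping[str, frozenset[str]] | None = None,
        cues: CueLexicon | None = None,
        table: EmbeddingTable | None = None,
        scheme: LabelScheme | None = None,
    ):
        self.concept_lexicon = concept_lexicon
        self.label_lexicon = label_lexicon
        self.cues = cues
        self.table = table
        self.scheme = scheme

    def fit(self, X=None, y=None):
        if not self.concept_lexicon or self.label_lexicon is None or self.table is None:
            raise ValueError("concept_lexicon, label_lexicon and table are required")
        self.scheme_ = self.scheme or LabelScheme.default()
        self.cues_ = self.cues or CueLexicon.default()
        return self

    def transform(self, X) -> list[PatientRepresentation]:
        check_is_fitted(self, "scheme_")
        reps, stats, _ = notes_to_representations(
            _as_notes(X), self.concept_lexicon, self.label_lexicon, self.cues_, self.table, self.scheme_
        )
        self.stats_ = stats
        return reps


class EMDPairwiseDistance(TransformerMixin, BaseEstimator):
    """Pairwise label-weighted earth mover's distances between representations.

    ``fit`` stores the reference representations; ``transform(X)``
    returns the |X| x |fit| rectangular distance matrix (NaN for
    incomparable pairs), so ``fit_transform(X)`` is the square matrix
    sklearn's ``metric='precomputed'`` consumers expect.
    """

    def __init__(
        self,
        label_subset: frozenset[str] | None = None,
        missing_label_mode: str = "intersection",
        penalty_value: float = 1.0,
    ):
        self.label_subset = label_subset
        self.missing_label_mode = missing_label_mode
        self.penalty_value = penalty_value

    def _config(self) -> GlobalDistanceConfig:
        return GlobalDistanceConfig(
            label_subset=frozenset(self.label_subset) if self.label_subset else None,
            missing_label_mode=self.missing_label_mode,
            penalty_value=self.penalty_value,
        )

    def fit(self, X: Sequence[PatientRepresentation], y=None):
        if len(X) < 1:
            raise ValueError("need at least one reference representation")
        self.reference_ = list(X)
        self.cache_: EMDCache = {}
        return self

    def transform(self, X: Sequence[PatientRepresentation]) -> np.ndarray:
        check_is_fitted(self, "reference_")
        cfg = self._config()
        out = np.full((len(X), len(self.reference_)), np.nan)
        for i, a in enumerate(X):
            for j, b in enumerate(self.reference_):
                if a.document_id == b.document_id:
                    out[i, j] = 0.0
                    continue
                try:
                    out[i, j] = global_distance(a, b, cfg, cache=self.cache_)
                except Exception:
                    pass  # NaN marks the incomparable pair
        return out


class WardCohortClustering(ClusterMixin, BaseEstimator):
    """Agglomerative Ward clustering of a precomputed distance matrix.

    ``fit(D)`` expects a square symmetric distance matrix (for instance
    from :class:`EMDPairwiseDistance`); fitted attributes are
    ``linkage_`` (the merge tree) and ``labels_`` (the ``n_clusters``
    flat cut).
    """

    def __init__(self, n_clusters: int = 2, ids: Sequence[str] | None = None):
        self.n_clusters = n_clusters
        self.ids = ids

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.linkage_: Linkage = ward_linkage(X, ids=self.ids)
        assignment = cut(self.linkage_, self.n_clusters)
        self.labels_ = np.asarray([assignment[doc] for doc in self.linkage_.ids])
        return self


class CohortRetriever(BaseEstimator):
    """Rank a fitted candidate pool by routed distance to an index patient.

    ``fit`` stores the candidate representations; :meth:`query` returns
    a :class:`~cohortsim.retrieval.RankedCohort` of distinct patients,
    optionally restricted to a phenotype's routed labels.
    """

    def __init__(
        self,
        labels: frozenset[str] | None = None,
        missing_label_mode: str = "intersection",
        penalty_value: float = 1.0,
    ):
        self.labels = labels
        self.missing_label_mode = missing_label_mode
        self.penalty_value = penalty_value

    def fit(self, X: Sequence[PatientRepresentation], y=None):
        if not X:
            raise ValueError("candidate pool is empty")
        self.candidates_ = list(X)
        self.cache_: EMDCache = {}
        return self

    def query(
        self, index: PatientRepresentation, labels: Iterable[str] | None = None
    ) -> RankedCohort:
        check_is_fitted(self, "candidates_")
        cfg = GlobalDistanceConfig(
            missing_label_mode=self.missing_label_mode, penalty_value=self.penalty_value
        )
        pool = [c for c in self.candidates_ if c.patient_id != index.patient_id]
        return rank_cohort(
            index, pool, labels=labels or self.labels, cfg=cfg, cache=self.cache_
        )
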