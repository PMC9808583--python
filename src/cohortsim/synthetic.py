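"""Self-contained synthetic corpora for exercising the whole pipeline.

Real annotated hospitalization reports cannot be shipped, so this module
generates corpora with the statistical structure the method assumes:

* a term vocabulary organised in per-(phenotype, label) pools plus a
  per-label pool of incidental background findings;
* an embedding geometry in which each pool is a Gaussian blob on the
  unit sphere, with blob separation controlled by a single parameter
  (``separation = 0`` collapses every pool onto one cluster, making the
  retrieval task uninformative by construction);
* multi-sentence French-like note text with the planted terms, a
  configurable fraction of decoy mentions wrapped in negation /
  hypothesis / family cues, and per-document gold phenotype labels;
* every lexicon and vector file the other stages consume.

Generation is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embeddings import EmbeddingTable, save_vectors
from .labels import write_label_lexicon
from .text import (
    FAMILY,
    HYPOTHETICAL,
    NEGATED,
    POSITIVE,
    ClinicalNote,
    CueLexicon,
    write_concept_lexicon,
    write_cue_lexicon,
    write_notes_jsonl,
)


@dataclass(frozen=True)
class PhenotypeSpec:
    """One planted phenotype: its prevalence and the labels it is routed to."""

    name: str
    prevalence: float
    labels: tuple[str, ...]
    pool_size: int = 30

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in (0, 1]")
        if not self.labels:
            raise ValueError("a phenotype needs at least one routed label")


def default_phenotypes() -> tuple[PhenotypeSpec, ...]:
    """Four phenotypes with the shipped label routings, prevalence 1/4 each."""
    return (
        PhenotypeSpec("osteoporosis", 0.25, ("musculoskeletal", "nutritional")),
        PhenotypeSpec("nephritis_sle", 0.25, ("urogenital", "immune")),
        PhenotypeSpec("ild_ssc", 0.25, ("respiratory", "immune")),
        PhenotypeSpec("lung_infection", 0.25, ("respiratory", "infections")),
    )


@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions of a synthetic corpus.

    ``separation`` scales the angular spread of the pool centroids on
    the unit sphere (0 = all pools coincide); ``intra_radius`` the
    within-pool jitter.  ``terms_per_label`` is the (inclusive) range of
    planted positive mentions per routed label of the note's phenotype.
    ``background_rate`` is the probability that, for each label outside
    its phenotype's routing, a note mentions a batch of incidental
    background findings (drawn with the same per-label count range as
    phenotype terms), so that document pairs stay comparable on any
    label and support size carries no phenotype signal.
    The cue fractions are the probabilities that a note contains one
    decoy mention wrapped in a cue of that class.
    """

    n_patients: int = 80
    phenotypes: tuple[PhenotypeSpec, ...] = field(default_factory=default_phenotypes)
    terms_per_label: tuple[int, int] = (2, 4)
    background_rate: float = 1.0
    negated_fraction: float = 0.2
    hypothetical_fraction: float = 0.1
    family_fraction: float = 0.05
    separation: float = 4.0
    intra_radius: float = 0.08
    dimension: int = 16
    background_pool_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if sum(p.prevalence for p in self.phenotypes) > 1.0 + 1e-9:
            raise ValueError("phenotype prevalences must sum to at most 1")
        lo, hi = self.terms_per_label
        if not (1 <= lo <= hi):
            raise ValueError("terms_per_label must be a non-empty positive range")
        for p in self.phenotypes:
            if p.pool_size < hi:
                raise ValueError(
                    f"phenotype {p.name!r}: pool_size {p.pool_size} < max terms per label {hi}"
                )
        for frac in (self.negated_fraction, self.hypothetical_fraction, self.family_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("cue fractions must lie in [0, 1]")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


@dataclass
class SyntheticCorpus:
    """A generated corpus plus the ground truth used to validate each stage."""

    config: CorpusConfig
    notes: list[ClinicalNote]
    concept_lexicon: dict[str, str]
    label_lexicon: dict[str, frozenset[str]]
    cues: CueLexicon
    table: EmbeddingTable
    gold: dict[str, set[str]]                     # document -> phenotypes
    planted: dict[str, list[tuple[str, str]]]     # document -> (canonical, assertion)
    routing: dict[str, frozenset[str]]

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Emit all files in the formats the pipeline stages consume."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "notes": directory / "notes.jsonl",
            "concept_lexicon": directory / "concept_lexicon.tsv",
            "label_lexicon": directory / "label_lexicon.tsv",
            "cues": directory / "cues.tsv",
            "vectors": directory / "vectors.w2v.txt",
            "gold": directory / "gold.tsv",
            "routing": directory / "routing.tsv",
        }
        write_notes_jsonl(self.notes, paths["notes"])
        write_concept_lexicon(self.concept_lexicon, paths["concept_lexicon"])
        write_label_lexicon(self.label_lexicon, paths["label_lexicon"])
        write_cue_lexicon(self.cues, paths["cues"])
        save_vectors(self.table, paths["vectors"])
        with open(paths["gold"], "w", encoding="utf-8") as fh:
            for doc in sorted(self.gold):
                for pheno in sorted(self.gold[doc]):
                    fh.write(f"{doc}\t{pheno}\n")
        with open(paths["routing"], "w", encoding="utf-8") as fh:
            for pheno in sorted(self.routing):
                fh.write(f"{pheno}\t{','.join(sorted(self.routing[pheno]))}\n")
        return paths


_POSITIVE_TEMPLATES = (
    "Le patient présente {t}.",
    "On retrouve {t} à l'examen.",
    "Le bilan montre {t}.",
    "Hospitalisation pour {t}.",
)
_CUE_TEMPLATES = {
    NEGATED: "Pas de {t}.",
    HYPOTHETICAL: "Suspicion de {t}.",
    FAMILY: "Antécédents familiaux de {t}.",
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_corpus(cfg: CorpusConfig) -> SyntheticCorpus:
    """Generate a corpus under the given study conditions (deterministic by seed)."""
    rng = np.random.default_rng(cfg.seed)

    all_labels = sorted({l for p in cfg.phenotypes for l in p.labels})
    pools: dict[tuple[str, str], list[str]] = {}       # (owner, label) -> terms
    for pheno in cfg.phenotypes:
        for label in pheno.labels:
            pools[(pheno.name, label)] = [
                f"{pheno.name}_{label}_t{j}" for j in range(pheno.pool_size)
            ]
    for label in all_labels:
        pools[("commun", label)] = [
            f"commun_{label}_t{j}" for j in range(cfg.background_pool_size)
        ]

    # embedding geometry: one spherical blob per pool
    anchor = _unit(rng.standard_normal(cfg.dimension))
    table = EmbeddingTable(dimension=cfg.dimension)
    centers: dict[tuple[str, str], np.ndarray] = {}
    for key in sorted(pools):
        center = _unit(anchor + cfg.separation * _unit(rng.standard_normal(cfg.dimension)))
        centers[key] = center
        for term in pools[key]:
            table.vectors[term] = _unit(center + cfg.intra_radius * rng.standard_normal(cfg.dimension))

    # per-label vocabulary matrices for nearest-term sampling
    label_vocab: dict[str, list[str]] = {}
    label_mat: dict[str, np.ndarray] = {}
    for (owner, label), terms in sorted(pools.items()):
        label_vocab.setdefault(label, []).extend(terms)
    for label, vocab in label_vocab.items():
        label_mat[label] = np.stack([table.vectors[t] for t in vocab])

    def draw_terms(owner: str, label: str, k: int) -> list[str]:
        """k mentions on one label: sample the blob, emit the nearest vocab term.

        Drawing through the embedding geometry (rather than from the pool's
        term list directly) makes term identity exactly as informative as the
        geometry itself: with zero separation every pool collapses onto one
        cluster and the drawn identities carry no phenotype signal at all.
        """
        center = centers[(owner, label)]
        out = []
        for _ in range(k):
            x = _unit(center + cfg.intra_radius * rng.standard_normal(cfg.dimension))
            out.append(label_vocab[label][int(np.argmax(label_mat[label] @ x))])
        return out

    concept_lexicon = {term: term for terms in pools.values() for term in terms}
    owner = {term: key[0] for key, terms in pools.items() for term in terms}
    label_lexicon = {
        term: frozenset({label}) for (_, label), terms in pools.items() for term in terms
    }
    cues = CueLexicon(
        negation_cues=("pas de", "sans", "absence de"),
        hypothesis_cues=("suspicion de", "doute sur"),
        family_cues=("antécédents familiaux de",),
        scope_window=5,
    )

    # deterministic phenotype assignment by quota, then shuffled order
    assignment: list[str | None] = []
    for pheno in cfg.phenotypes:
        assignment.extend([pheno.name] * round(pheno.prevalence * cfg.n_patients))
    assignment.extend([None] * (cfg.n_patients - len(assignment)))
    if len(assignment) != cfg.n_patients:
        raise ValueError("phenotype quotas exceed the number of patients")
    rng.shuffle(assignment)

    by_name = {p.name: p for p in cfg.phenotypes}
    notes: list[ClinicalNote] = []
    gold: dict[str, set[str]] = {}
    planted: dict[str, list[tuple[str, str]]] = {}
    decoy_vocab = sorted(concept_lexicon)
    for idx in range(cfg.n_patients):
        patient_id = f"pat{idx:03d}"
        document_id = f"doc{idx:03d}"
        pheno_name = assignment[idx]
        sentences: list[str] = []
        truth: list[tuple[str, str]] = []
        own_labels: tuple[str, ...] = ()
        if pheno_name is not None:
            pheno = by_name[pheno_name]
            own_labels = pheno.labels
            for label in pheno.labels:
                k = int(rng.integers(cfg.terms_per_label[0], cfg.terms_per_label[1] + 1))
                for term in draw_terms(pheno.name, label, k):
                    template = _POSITIVE_TEMPLATES[int(rng.integers(len(_POSITIVE_TEMPLATES)))]
                    sentences.append(template.format(t=str(term)))
                    truth.append((str(term), POSITIVE))
        for label in all_labels:
            if label in own_labels:
                continue
            if rng.random() < cfg.background_rate:
                # incidental findings mirror the per-label count structure of the
                # planted phenotype terms, so document support sizes carry no signal
                k = int(rng.integers(cfg.terms_per_label[0], cfg.terms_per_label[1] + 1))
                for term in draw_terms("commun", label, k):
                    template = _POSITIVE_TEMPLATES[int(rng.integers(len(_POSITIVE_TEMPLATES)))]
                    sentences.append(template.format(t=str(term)))
                    truth.append((str(term), POSITIVE))
        for assertion, frac in (
            (NEGATED, cfg.negated_fraction),
            (HYPOTHETICAL, cfg.hypothetical_fraction),
            (FAMILY, cfg.family_fraction),
        ):
            if rng.random() < frac:
                # decoys never come from the note's own phenotype pools, so a
                # planted phenotype term can never appear only under a cue
                positive_terms = {t for t, a in truth if a == POSITIVE}
                choices = [
                    t
                    for t in decoy_vocab
                    if t not in positive_terms and owner[t] != pheno_name
                ]
                term = str(choices[int(rng.integers(len(choices)))])
                sentences.append(_CUE_TEMPLATES[assertion].format(t=term))
                truth.append((term, assertion))
        rng.shuffle(sentences)
        notes.append(ClinicalNote(document_id, patient_id, " ".join(sentences)))
        gold[document_id] = {pheno_name} if pheno_name is not None else set()
        planted[document_id] = truth

    routing = {p.name: frozenset(p.labels) for p in cfg.phenotypes}
    return SyntheticCorpus(
        config=cfg,
        notes=notes,
        concept_lexicon=concept_lexicon,
        label_lexicon=label_lexicon,
        cues=cues,
        table=table,
        gold=gold,
        planted=planted,
        routing=routing,
    )


GOLDEN_CONFIG = CorpusConfig(
    n_patients=12,
    phenotypes=(
        PhenotypeSpec("osteoporosis", 0.5, ("musculoskeletal", "nutritional"), pool_size=4),
        PhenotypeSpec("nephritis_sle", 0.5, ("urogenital", "immune"), pool_size=4),
    ),
    terms_per_label=(1, 3),
    background_rate=1.0,
    negated_fraction=0.3,
    hypothetical_fraction=0.2,
    family_fraction=0.1,
    separation=3.0,
    dimension=8,
    background_pool_size=3,
    seed=1729,
)


def golden_corpus() -> SyntheticCorpus:
    """The packaged miniature corpus (12 notes, 2 phenotypes) with frozen outputs."""
    return generate_corpus(GOLDEN_CONFIG)
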