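"""End-to-end orchestration: notes -> representations -> distances -> reports.

Thin glue over the stage modules, plus the canonical artifact layout
used by the command-line interface and the frozen miniature corpus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .cluster import ward_linkage
from .embeddings import EmbeddingTable
from .labels import LabelScheme, aggregate_terms
from .patient import (
    PatientRepresentation,
    build_representation,
    write_representations_jsonl,
)
from .retrieval import evaluate_phenotypes, write_metric_report
from .similarity import GlobalDistanceConfig, distance_matrix
from .synthetic import SyntheticCorpus, golden_corpus
from .text import (
    ClinicalNote,
    CueLexicon,
    assert_mentions,
    extract_mentions,
    filter_positive,
    write_mentions_jsonl,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineStats:
    n_mentions: int = 0
    n_positive: int = 0
    n_dropped_unlabelable: int = 0
    per_document: dict[str, dict[str, int]] = field(default_factory=dict)


def notes_to_representations(
    notes: Sequence[ClinicalNote],
    concept_lexicon: Mapping[str, str],
    label_lexicon: Mapping[str, frozenset[str]],
    cues: CueLexicon,
    table: EmbeddingTable,
    scheme: LabelScheme | None = None,
) -> tuple[list[PatientRepresentation], PipelineStats, list[tuple[str, list]]]:
    """Run extraction, assertion filtering, labeling and embedding for all notes.

    Returns the representations, bookkeeping statistics, and the full
    per-document asserted mention lists (useful for audit output).
    """
    scheme = scheme or LabelScheme.default()
    stats = PipelineStats()
    reps: list[PatientRepresentation] = []
    doc_mentions: list[tuple[str, list]] = []
    for note in notes:
        asserted = assert_mentions(note, extract_mentions(note, concept_lexicon), cues)
        positive = filter_positive(asserted)
        terms, dropped = aggregate_terms(positive, label_lexicon, scheme)
        reps.append(build_representation(note, terms, table))
        doc_mentions.append((note.document_id, asserted))
        stats.n_mentions += len(asserted)
        stats.n_positive += len(positive)
        stats.n_dropped_unlabelable += dropped
        stats.per_document[note.document_id] = {
            "mentions": len(asserted),
            "positive": len(positive),
            "dropped_unlabelable": dropped,
        }
    if stats.n_dropped_unlabelable:
        logger.info(
            "%d positive mention(s) dropped as unlabelable", stats.n_dropped_unlabelable
        )
    return reps, stats, doc_mentions


def run_corpus_pipeline(
    corpus: SyntheticCorpus,
    outdir: str | Path,
    n_clusters: int = 2,
    cfg: GlobalDistanceConfig | None = None,
) -> dict[str, Path]:
    """Full pipeline over an in-memory corpus, writing the canonical artifacts.

    Artifacts: asserted mentions (JSONL), representations (JSONL), the
    global distance matrix (CSV), Ward linkage (CSV) with a Newick
    dendrogram, one ranked table per phenotype for the first gold-positive
    index document, and the rotation-averaged metric report (JSON).
    """
    from .retrieval import format_ranked_table, rank_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = LabelScheme(tuple(sorted({l for ls in corpus.label_lexicon.values() for l in ls})))
    reps, stats, doc_mentions = notes_to_representations(
        corpus.notes, corpus.concept_lexicon, corpus.label_lexicon, corpus.cues, corpus.table, scheme
    )
    paths: dict[str, Path] = {}

    paths["mentions"] = outdir / "mentions.jsonl"
    write_mentions_jsonl(doc_mentions, paths["mentions"])

    paths["representations"] = outdir / "representations.jsonl"
    write_representations_jsonl(reps, paths["representations"])

    dm = distance_matrix(reps, cfg)
    paths["distance"] = outdir / "distance.csv"
    dm.to_csv(paths["distance"])

    linkage = ward_linkage(dm)
    paths["linkage"] = outdir / "linkage.csv"
    linkage.to_csv(paths["linkage"])
    paths["dendrogram"] = outdir / "dendrogram.nwk"
    linkage.to_newick(paths["dendrogram"])

    evaluations = evaluate_phenotypes(reps, corpus.gold, routing=corpus.routing)
    paths["metrics"] = outdir / "metrics.json"
    write_metric_report(evaluations, paths["metrics"])

    by_doc = {r.document_id: r for r in reps}
    cache: dict = {}
    for pheno in sorted(corpus.routing):
        positives = sorted(d for d, phenos in corpus.gold.items() if pheno in phenos)
        if not positives:
            continue
        index = by_doc[positives[0]]
        candidates = [r for r in reps if r.patient_id != index.patient_id]
        cohort = rank_cohort(
            index, candidates, labels=corpus.routing[pheno], cfg=cfg, cache=cache
        ).with_relevance(
            {by_doc[d].patient_id for d in positives}
        )
        paths[f"ranked_{pheno}"] = outdir / f"ranked_{pheno}.txt"
        paths[f"ranked_{pheno}"].write_text(format_ranked_table(cohort), encoding="utf-8")

    paths["stats"] = outdir / "stats.json"
    paths["stats"].write_text(
        json.dumps(
            {
                "n_mentions": stats.n_mentions,
                "n_positive": stats.n_positive,
                "n_dropped_unlabelable": stats.n_dropped_unlabelable,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return paths


GOLDEN_ARTIFACTS = (
    "mentions.jsonl",
    "representations.jsonl",
    "distance.csv",
    "linkage.csv",
    "dendrogram.nwk",
    "metrics.json",
    "stats.json",
    "ranked_nephritis_sle.txt",
    "ranked_osteoporosis.txt",
)


def run_golden_pipeline(outdir: str | Path) -> dict[str, Path]:
    """Run the full pipeline on the packaged miniature corpus."""
    return run_corpus_pipeline(golden_corpus(), outdir)
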