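"""Planted-structure validation studies.

These functions run the full pipeline on generated corpora and summarise
retrieval quality, so the behaviour of the distance can be checked in
the two regimes where the answer is known: with well-separated phenotype
term clusters retrieval should be near-perfect, and with zero separation
the ranking carries no signal, so average precision should fall back to
the phenotype's prevalence among comparable candidates.
"""

from __future__ import annotations

from dataclasses import replace
import numpy as np

from .labels import LabelScheme
from .pipeline import notes_to_representations
from .retrieval import evaluate_phenotypes
from .synthetic import CorpusConfig, generate_corpus


def corpus_retrieval_metrics(cfg: CorpusConfig) -> dict[str, dict[str, float]]:
    """Run the pipeline on one generated corpus; mean metrics per phenotype."""
    corpus = generate_corpus(cfg)
    scheme = LabelScheme(tuple(sorted({l for ls in corpus.label_lexicon.values() for l in ls})))
    reps, _, _ = notes_to_representations(
        corpus.notes, corpus.concept_lexicon, corpus.label_lexicon, corpus.cues, corpus.table, scheme
    )
    evaluations = evaluate_phenotypes(reps, corpus.gold, routing=corpus.routing)
    return {
        pheno: {name: summary.mean for name, summary in ev.metrics.items()}
        for pheno, ev in evaluations.items()
    }


def planted_retrieval_study(
    seeds: list[int], base: CorpusConfig | None = None
) -> dict[str, dict[str, float]]:
    """Seed-averaged retrieval metrics per phenotype under the given conditions."""
    base = base or CorpusConfig()
    acc: dict[str, dict[str, list[float]]] = {}
    for seed in seeds:
        per_pheno = corpus_retrieval_metrics(replace(base, seed=seed))
        for pheno, metrics in per_pheno.items():
            for name, value in metrics.items():
                acc.setdefault(pheno, {}).setdefault(name, []).append(value)
    return {
        pheno: {name: float(np.mean(vals)) for name, vals in metrics.items()}
        for pheno, metrics in acc.items()
    }


def null_separation_ap(seeds: list[int], base: CorpusConfig | None = None) -> float:
    """Mean average precision over seeds with zero cluster separation.

    With all term pools collapsed onto one embedding cluster the ranking
    is uninformative; the expected AP is the phenotype prevalence among
    comparable candidates.
    """
    base = replace(base or CorpusConfig(), separation=0.0)
    aps = []
    for seed in seeds:
        per_pheno = corpus_retrieval_metrics(replace(base, seed=seed))
        aps.extend(m["average_precision"] for m in per_pheno.values())
    return float(np.mean(aps))


def expected_null_ap(cfg: CorpusConfig | None = None) -> float:
    """Prevalence of one phenotype among a rotation's candidate patients."""
    cfg = cfg or CorpusConfig()
    prevalence = cfg.phenotypes[0].prevalence
    n_pos = round(prevalence * cfg.n_patients)
    return (n_pos - 1) / (cfg.n_patients - 1)
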