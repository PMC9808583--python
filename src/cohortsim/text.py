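"""Reference concept extraction and assertion filtering.

The pipeline's first stage finds symptom/disorder mentions in a raw
hospitalization report and keeps only *positive* findings: anything
negated ("pas de fièvre"), hypothetical ("suspicion d'angioedème") or
attributed to a relative is discarded before the patient representation
is built.

The extractor shipped here is a deterministic gazetteer with a
NegEx-style forward cue scope.  It exists so the whole pipeline is
runnable and testable end to end; any extractor producing the same
``(note) -> asserted mentions`` contract (e.g. a neural NER system) can
be swapped in without touching downstream stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from ._normalize import (
    SENTENCE_BOUNDARY_CHARS,
    find_folded,
    fold,
    fold_with_map,
    token_index_at_or_after,
    token_starts,
)
from .errors import LexiconError, PipelineOrderError

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATED = "negated"
HYPOTHETICAL = "hypothetical"
FAMILY = "family"
ASSERTIONS = (POSITIVE, NEGATED, HYPOTHETICAL, FAMILY)


@dataclass(frozen=True)
class ClinicalNote:
    """One hospitalization report: the unit of comparison for the whole method."""

    document_id: str
    patient_id: str
    text: str


@dataclass(frozen=True)
class TermMention:
    """A matched concept span; ``assertion`` is None until :func:`assert_mentions` runs."""

    surface: str
    canonical: str
    start: int
    end: int
    assertion: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.assertion is not None and self.assertion not in ASSERTIONS:
            raise ValueError(f"unknown assertion {self.assertion!r}")


@dataclass(frozen=True)
class CueLexicon:
    """Trigger phrases for negation / hypothesis / family attribution.

    A cue projects forward over ``scope_window`` word tokens, terminated
    by a sentence boundary (``.``, ``;`` or newline).
    """

    negation_cues: tuple[str, ...]
    hypothesis_cues: tuple[str, ...]
    family_cues: tuple[str, ...]
    scope_window: int = 5

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")

    @classmethod
    def default(cls) -> "CueLexicon":
        from .resources import default_cue_lexicon

        return default_cue_lexicon()


# ---------------------------------------------------------------------------
# lexicon / note file formats
# ---------------------------------------------------------------------------


def read_notes_jsonl(path: str | Path) -> list[ClinicalNote]:
    """Read notes from JSON-lines with keys document_id, patient_id, text."""
    notes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                notes.append(
                    ClinicalNote(str(obj["document_id"]), str(obj["patient_id"]), obj["text"])
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed note record: {exc}") from exc
    return notes


def write_notes_jsonl(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {"document_id": n.document_id, "patient_id": n.patient_id, "text": n.text},
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_concept_lexicon(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV ``surface<TAB>canonical`` map ('#' comments allowed).

    Malformed rows are reported with their line number and skipped.
    """
    lexicon: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                logger.warning("%s:%d: malformed concept lexicon row skipped: %r", path, lineno, line)
                continue
            lexicon[parts[0].strip()] = parts[1].strip()
    return lexicon


def write_concept_lexicon(lexicon: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for surface in sorted(lexicon):
            fh.write(f"{surface}\t{lexicon[surface]}\n")


_CUE_CLASSES = {"negation": "negation_cues", "hypothesis": "hypothesis_cues", "family": "family_cues"}


def read_cue_lexicon(path: str | Path, scope_window: int = 5) -> CueLexicon:
    """Read a 2-column TSV ``cue<TAB>{negation|hypothesis|family}``."""
    cues: dict[str, list[str]] = {v: [] for v in _CUE_CLASSES.values()}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1].strip() not in _CUE_CLASSES:
                raise LexiconError(f"{path}:{lineno}: malformed cue row: {line!r}")
            cues[_CUE_CLASSES[parts[1].strip()]].append(parts[0].strip())
    return CueLexicon(
        negation_cues=tuple(cues["negation_cues"]),
        hypothesis_cues=tuple(cues["hypothesis_cues"]),
        family_cues=tuple(cues["family_cues"]),
        scope_window=scope_window,
    )


def write_cue_lexicon(cues: CueLexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for attr, cls in (("negation_cues", "negation"), ("hypothesis_cues", "hypothesis"), ("family_cues", "family")):
            for cue in getattr(cues, attr):
                fh.write(f"{cue}\t{cls}\n")


def write_mentions_jsonl(
    doc_mentions: Iterable[tuple[str, Iterable[TermMention]]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for document_id, mentions in doc_mentions:
            for m in mentions:
                fh.write(
                    json.dumps(
                        {
                            "document_id": document_id,
                            "canonical": m.canonical,
                            "surface": m.surface,
                            "start": m.start,
                            "end": m.end,
                            "assertion": m.assertion,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_mentions(note: ClinicalNote, concept_lexicon: Mapping[str, str]) -> list[TermMention]:
    """Find all lexicon concepts in a note, longest-match-wins on overlaps.

    Matching is case- and accent-insensitive; offsets refer to the
    original text.  Returned mentions are non-overlapping and sorted by
    start offset, with ``assertion`` unset.
    """
    if not concept_lexicon:
        raise LexiconError("concept lexicon is empty")
    if not note.text:
        return []
    folded, back = fold_with_map(note.text)
    candidates: list[tuple[int, int, str]] = []  # (orig start, orig end, canonical)
    for surface, canonical in concept_lexicon.items():
        fsurf = fold(surface)
        for fs, fe in find_folded(folded, fsurf):
            start = back[fs]
            end = back[fe - 1] + 1
            candidates.append((start, end, canonical))
    # longest span wins; among equal lengths leftmost wins
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    chosen: list[tuple[int, int, str]] = []
    for start, end, canonical in candidates:
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, canonical))
    chosen.sort(key=lambda c: c[0])
    return [
        TermMention(surface=note.text[s:e], canonical=canon, start=s, end=e)
        for s, e, canon in chosen
    ]


def _cue_spans(note_text: str, folded: str, back: list[int], cues: Iterable[str]) -> list[int]:
    """End offsets (original coordinates) of every cue occurrence."""
    ends = []
    for cue in cues:
        for fs, fe in find_folded(folded, fold(cue)):
            ends.append(back[fe - 1] + 1)
    return ends


def assert_mentions(
    note: ClinicalNote, mentions: list[TermMention], cues: CueLexicon
) -> list[TermMention]:
    """Set each mention's assertion from cue scope.

    A mention within ``scope_window`` tokens after a cue, with no
    sentence boundary in between, takes that cue's assertion class.
    Precedence when several classes apply: negated > family >
    hypothetical; otherwise positive.
    """
    folded, back = fold_with_map(note.text)
    starts = token_starts(note.text)
    classes = (
        (NEGATED, cues.negation_cues),
        (FAMILY, cues.family_cues),
        (HYPOTHETICAL, cues.hypothesis_cues),
    )
    class_ends = {label: _cue_spans(note.text, folded, back, cue_list) for label, cue_list in classes}

    out: list[TermMention] = []
    for m in mentions:
        assertion = POSITIVE
        m_tok = token_index_at_or_after(starts, m.start)
        for label, _ in classes:
            hit = False
            for cue_end in class_ends[label]:
                if cue_end > m.start:
                    continue
                between = note.text[cue_end : m.start]
                if any(c in SENTENCE_BOUNDARY_CHARS for c in between):
                    continue
                offset = m_tok - token_index_at_or_after(starts, cue_end)
                if 0 <= offset < cues.scope_window:
                    hit = True
                    break
            if hit:
                assertion = label
                break
        out.append(dataclasses.replace(m, assertion=assertion))
    return out


def filter_positive(mentions: list[TermMention]) -> list[TermMention]:
    """Keep only positively asserted mentions, order preserved."""
    for m in mentions:
        if m.assertion is None:
            raise PipelineOrderError(
                f"mention {m.canonical!r} has no assertion; run assert_mentions first"
            )
    return [m for m in mentions if m.assertion == POSITIVE]


def extract_positive_mentions(
    note: ClinicalNote, concept_lexicon: Mapping[str, str], cues: CueLexicon
) -> list[TermMention]:
    """Convenience: extract, assert, and keep positive mentions of one note."""
    return filter_positive(assert_mentions(note, extract_mentions(note, concept_lexicon), cues))
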