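"""Organ-system labeling of extracted terms.

Each positive canonical term is mapped to one or more of the 22 MeSH
category-C head chapters (infections, cardiovascular, immune, skin, ...)
used as broad medical-field labels.  The reference implementation is a
term -> labels lexicon behind a classifier-agnostic interface: a trained
multilabel classifier can replace it as long as it produces the same
``canonical -> set of labels`` mapping.

Mental-health chapters are deliberately absent from the default scheme;
the scheme is a plain text file, so extending it is trivial.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import LexiconError
from .text import TermMention

FrozenLabels = frozenset


@dataclass(frozen=True)
class LabelScheme:
    """Ordered universe of label names (default: 22 MeSH-C head chapters)."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("label names must be unique")

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def default(cls) -> "LabelScheme":
        from .resources import default_label_scheme

        return default_label_scheme()

    @classmethod
    def from_file(cls, path: str | Path) -> "LabelScheme":
        with open(path, encoding="utf-8") as fh:
            labels = tuple(line.strip() for line in fh if line.strip() and not line.startswith("#"))
        return cls(labels)


@dataclass(frozen=True)
class LabeledTerm:
    """A distinct canonical term with its labels and occurrence count in one document."""

    canonical: str
    labels: frozenset[str]
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.labels:
            raise ValueError("labels must be non-empty")


def read_label_lexicon(
    path: str | Path, scheme: LabelScheme | None = None
) -> dict[str, frozenset[str]]:
    """Read a TSV ``canonical<TAB>comma-separated-labels`` lexicon."""
    lexicon: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip():
                raise LexiconError(f"{path}:{lineno}: malformed label lexicon row: {line!r}")
            labels = frozenset(l.strip() for l in parts[1].split(",") if l.strip())
            if scheme is not None:
                unknown = labels - set(scheme.labels)
                if unknown:
                    raise LexiconError(
                        f"{path}:{lineno}: label {sorted(unknown)[0]!r} not in scheme"
                    )
            lexicon[parts[0].strip()] = labels
    return lexicon


def write_label_lexicon(lexicon: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for canonical in sorted(lexicon):
            fh.write(f"{canonical}\t{','.join(sorted(lexicon[canonical]))}\n")


def label_term(
    canonical: str, label_lexicon: Mapping[str, frozenset[str]], scheme: LabelScheme
) -> frozenset[str]:
    """Labels of one canonical term; empty set when the term is unlabelable.

    A lexicon entry naming a label outside the scheme is an error (the
    lexicon and scheme are inconsistent, which should not pass silently).
    """
    labels = frozenset(label_lexicon.get(canonical, frozenset()))
    unknown = labels - set(scheme.labels)
    if unknown:
        raise LexiconError(
            f"term {canonical!r} carries label {sorted(unknown)[0]!r} outside the scheme"
        )
    return labels


def aggregate_terms(
    mentions: Iterable[TermMention],
    label_lexicon: Mapping[str, frozenset[str]],
    scheme: LabelScheme,
) -> tuple[list[LabeledTerm], int]:
    """Count positive mentions per canonical term and attach labels.

    Returns ``(labeled_terms, n_dropped)`` where ``n_dropped`` counts the
    mentions of terms with no label in the scheme (they cannot enter any
    per-label distance and are excluded from the representation).
    Conservation: sum of counts + n_dropped == number of input mentions.
    """
    counts: Counter[str] = Counter()
    order: list[str] = []
    for m in mentions:
        if m.canonical not in counts:
            order.append(m.canonical)
        counts[m.canonical] += 1
    terms: list[LabeledTerm] = []
    dropped = 0
    for canonical in order:
        labels = label_term(canonical, label_lexicon, scheme)
        if labels:
            terms.append(LabeledTerm(canonical=canonical, labels=labels, count=counts[canonical]))
        else:
            dropped += counts[canonical]
    return terms, dropped
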