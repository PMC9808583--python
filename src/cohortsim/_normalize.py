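"""Case/accent folding with offset maps.

Lexicon and cue matching must be insensitive to casing and diacritics
(French clinical text mixes "Oedème", "oedeme", "OEDEME") while every
reported span still indexes the *original* text.  Folding therefore
returns, alongside the folded string, a map from each folded character
back to the index of the original character it came from.
"""

from __future__ import annotations

import re
import unicodedata
from bisect import bisect_left

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)

#: characters that terminate the forward scope of an assertion cue
SENTENCE_BOUNDARY_CHARS = ".;\n"


def fold_with_map(text: str) -> tuple[str, list[int]]:
    """Casefold + strip combining marks; return (folded, folded->original index map)."""
    chars: list[str] = []
    back: list[int] = []
    for i, ch in enumerate(text):
        for c in unicodedata.normalize("NFKD", ch.casefold()):
            if unicodedata.combining(c):
                continue
            chars.append(c)
            back.append(i)
    return "".join(chars), back


def fold(text: str) -> str:
    return fold_with_map(text)[0]


def is_word_char(c: str) -> bool:
    return c.isalnum() or c == "_"


def token_starts(text: str) -> list[int]:
    """Start offsets of whitespace/punctuation-delimited word tokens."""
    return [m.start() for m in _TOKEN_RE.finditer(text)]


def token_index_at_or_after(starts: list[int], offset: int) -> int:
    """Index of the first token starting at or after ``offset``."""
    return bisect_left(starts, offset)


def find_folded(haystack_folded: str, needle_folded: str) -> list[tuple[int, int]]:
    """All word-boundary-respecting occurrences of a folded needle.

    Returns (start, end) pairs in *folded* coordinates.  A match is kept
    only when not embedded in a longer word token on either side.
    """
    if not needle_folded:
        return []
    spans: list[tuple[int, int]] = []
    start = haystack_folded.find(needle_folded)
    n = len(haystack_folded)
    while start != -1:
        end = start + len(needle_folded)
        left_ok = start == 0 or not (
            is_word_char(haystack_folded[start - 1]) and is_word_char(needle_folded[0])
        )
        right_ok = end == n or not (
            is_word_char(haystack_folded[end - 1]) and is_word_char(haystack_folded[end])
        )
        if left_ok and right_ok:
            spans.append((start, end))
        start = haystack_folded.find(needle_folded, start + 1)
    return spans
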