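"""Dictionary matching in raw (unsegmented) text and post-level risk scoring.

Chinese microblog text carries no word boundaries, so lexicon words are
found by a character-level scan rather than by segmenting first.  Two scan
modes are provided:

``leftmost_longest``
    Scan left to right; at each position emit the longest lexicon word
    starting there and resume after its end.  Occurrences never overlap and
    a nested word (死 inside 想死) is not double-counted.

``all_occurrences``
    Every substring equal to a lexicon word is emitted, overlaps allowed —
    the counting convention of LIWC-style closed-vocabulary tools.

Matching is case-insensitive for cased (Latin) characters and exact for
CJK; both lexicon words and text are NFC-normalized before comparison.

A post's risk score is the sum of the weights of all matched occurrences;
a post whose score reaches the threshold (default 3) is flagged risky, so
a single heavy (weight-3) word suffices.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Mapping, Sequence

from .lexicon import LexiconEntry, SuicideLexicon

MODES = ("leftmost_longest", "all_occurrences")

DEFAULT_RISK_THRESHOLD = 3


class MatcherError(ValueError):
    pass


def _normalize(text: str) -> str:
    """NFC-normalize and lowercase per character.

    Lowercasing is applied character by character and skipped for the rare
    characters whose lowercase form changes length, so offsets into the
    normalized string stay aligned one-to-one with its characters.
    """
    text = unicodedata.normalize("NFC", text)
    out = []
    for ch in text:
        low = ch.lower()
        out.append(low if len(low) == 1 else ch)
    return "".join(out)


@dataclass(frozen=True)
class MatchOccurrence:
    """One lexicon-word hit: the word, its category/weight, and the
    half-open character span [start, end) in the normalized text."""

    word: str
    category: str
    weight: int
    start: int
    end: int


@dataclass(frozen=True)
class PostScore:
    """Per-post match result: occurrences, weight sum, category tallies and
    the risky flag (total_score >= threshold)."""

    occurrences: tuple[MatchOccurrence, ...]
    total_score: int
    category_counts: Mapping[str, int]
    is_risky: bool


class Matcher:
    """Immutable multi-pattern matcher over a lexicon.

    Results are a pure function of (lexicon, mode, text).
    """

    def __init__(self, lexicon: SuicideLexicon, mode: str = "leftmost_longest") -> None:
        if mode not in MODES:
            raise MatcherError(f"mode must be one of {MODES}, got {mode!r}")
        if len(lexicon) == 0:
            raise MatcherError("cannot build a matcher from an empty lexicon")
        self.mode = mode
        # normalized word -> entry; on the (unlikely) normalization collision
        # the higher-weight entry wins, ties to the lexicographically smaller word
        table: dict[str, LexiconEntry] = {}
        for e in lexicon:
            key = _normalize(e.word)
            prev = table.get(key)
            if prev is None or (e.weight, prev.word) > (prev.weight, e.word):
                table[key] = e
        self._table = table
        self._lengths = tuple(sorted({len(w) for w in table}, reverse=True))
        self._max_len = self._lengths[0]

    def find_matches(self, text: str) -> list[MatchOccurrence]:
        """All lexicon-word occurrences in ``text`` under this matcher's mode.

        Output is sorted by start offset, ties broken by descending length.
        Empty text yields an empty list.
        """
        norm = _normalize(text)
        n = len(norm)
        out: list[MatchOccurrence] = []
        if self.mode == "leftmost_longest":
            i = 0
            while i < n:
                hit = None
                for length in self._lengths:
                    if i + length > n:
                        continue
                    entry = self._table.get(norm[i : i + length])
                    if entry is not None:
                        hit = (entry, length)
                        break
                if hit is None:
                    i += 1
                else:
                    entry, length = hit
                    out.append(
                        MatchOccurrence(entry.word, entry.category, entry.weight, i, i + length)
                    )
                    i += length
        else:  # all_occurrences
            for i in range(n):
                for length in self._lengths:
                    if i + length > n:
                        continue
                    entry = self._table.get(norm[i : i + length])
                    if entry is not None:
                        out.append(
                            MatchOccurrence(entry.word, entry.category, entry.weight, i, i + length)
                        )
        out.sort(key=lambda m: (m.start, -(m.end - m.start)))
        return out


def build_matcher(lexicon: SuicideLexicon, mode: str = "leftmost_longest") -> Matcher:
    """Construct a :class:`Matcher`; raises on an empty lexicon."""
    return Matcher(lexicon, mode)


def score_post(
    occurrences: Sequence[MatchOccurrence],
    threshold: int = DEFAULT_RISK_THRESHOLD,
    unique_words: bool = False,
) -> PostScore:
    """Sum occurrence weights into a post risk score.

    Every occurrence counts by default (frequency-weighted summation);
    ``unique_words=True`` counts each distinct word once, provided for
    sensitivity analysis.  The post is flagged risky when the total reaches
    ``threshold``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if unique_words:
        seen: dict[str, MatchOccurrence] = {}
        for m in occurrences:
            seen.setdefault(m.word, m)
        counted: Sequence[MatchOccurrence] = list(seen.values())
    else:
        counted = occurrences
    total = sum(m.weight for m in counted)
    counts: dict[str, int] = {}
    for m in counted:
        counts[m.category] = counts.get(m.category, 0) + 1
    return PostScore(
        occurrences=tuple(occurrences),
        total_score=total,
        category_counts=counts,
        is_risky=total >= threshold,
    )
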