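"""Weighted risk lexicon: data model, TSV I/O, vote-based filtering, merging.

A risk lexicon is a set of words, each carrying one of 13 risk-related
categories and an integer sensitivity weight from 1 ("light") to 3
("heavy").  Entries additionally record their provenance — ``seed`` for
words retained from the initial expert selection, ``expanded`` for words
added later by corpus-based expansion — and, optionally, a corpus
frequency used for low-frequency filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: The 13 category labels, in fixed enumeration order.  Feature vectors and
#: summary tables follow this order.
CATEGORIES: tuple[str, ...] = (
    "suicide_ideation",
    "suicide_behavior",
    "psychache",
    "mental_illness",
    "hopeless",
    "somatic_complaints",
    "self_regulation",
    "personality",
    "stress",
    "trauma_hurt",
    "talk_about_others",
    "shame_guilt",
    "anger_hostility",
)

VALID_WEIGHTS = frozenset({1, 2, 3})
VALID_SOURCES = frozenset({"seed", "expanded"})

LEXICON_COLUMNS = ("word", "category", "weight", "source", "corpus_frequency")
VOTE_COLUMNS = ("word", "coder_id", "decision", "proposed_category", "proposed_weight")


class LexiconError(ValueError):
    """Raised for malformed lexicon entries or files."""


@dataclass(frozen=True)
class LexiconEntry:
    """One weighted lexicon word: the triple (word, category, weight).

    Parameters
    ----------
    word:
        Non-empty string without whitespace or tab characters; any script.
    category:
        One of the 13 labels in :data:`CATEGORIES`.
    weight:
        Sensitivity weight in {1, 2, 3}; heavier words are more sensitive
        indicators of risk.
    source:
        ``"seed"`` or ``"expanded"``.
    corpus_frequency:
        Optional non-negative occurrence count in a reference corpus.
    """

    word: str
    category: str
    weight: int
    source: str = "seed"
    corpus_frequency: int | None = None

    def __post_init__(self) -> None:
        if not self.word:
            raise LexiconError("word must be non-empty")
        if any(ch.isspace() for ch in self.word):
            raise LexiconError(f"word contains whitespace: {self.word!r}")
        if self.category not in CATEGORIES:
            raise LexiconError(f"unknown category: {self.category!r}")
        if self.weight not in VALID_WEIGHTS:
            raise LexiconError(f"weight must be 1, 2 or 3, got {self.weight!r}")
        if self.source not in VALID_SOURCES:
            raise LexiconError(f"source must be 'seed' or 'expanded', got {self.source!r}")
        if self.corpus_frequency is not None and self.corpus_frequency < 0:
            raise LexiconError("corpus_frequency must be non-negative")


@dataclass(frozen=True)
class VoteRecord:
    """One coder's decision on one word.

    ``decision`` is ``"eliminate"`` or ``"keep"``.  A vote may additionally
    propose a category and/or weight override, applied during expansion
    review when a quorum of coders propose the identical override.
    """

    word: str
    coder_id: str
    decision: str
    proposed_category: str | None = None
    proposed_weight: int | None = None

    def __post_init__(self) -> None:
        if self.decision not in ("eliminate", "keep"):
            raise LexiconError(f"decision must be 'eliminate' or 'keep', got {self.decision!r}")
        if self.proposed_category is not None and self.proposed_category not in CATEGORIES:
            raise LexiconError(f"unknown proposed_category: {self.proposed_category!r}")
        if self.proposed_weight is not None and self.proposed_weight not in VALID_WEIGHTS:
            raise LexiconError(f"proposed_weight must be 1, 2 or 3, got {self.proposed_weight!r}")


@dataclass
class SuicideLexicon:
    """A set of :class:`LexiconEntry` with unique words.

    Iteration order is insertion order, which file round-trips preserve.
    """

    entries: list[LexiconEntry] = field(default_factory=list)
    version: str = "0"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.word in seen:
                raise LexiconError(f"duplicate word in lexicon: {e.word!r}")
            seen.add(e.word)
        self._index: dict[str, LexiconEntry] = {e.word: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __getitem__(self, word: str) -> LexiconEntry:
        return self._index[word]

    @property
    def words(self) -> frozenset[str]:
        return frozenset(self._index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SuicideLexicon):
            return NotImplemented
        return self.entries == other.entries and self.version == other.version


def summarize(lexicon: SuicideLexicon) -> dict:
    """Summary table: per-category counts, per-weight counts and total.

    Both the category counts and the weight counts sum to the total size,
    mirroring the published outline table of the dictionary.
    """
    by_category = {c: 0 for c in CATEGORIES}
    by_weight = {1: 0, 2: 0, 3: 0}
    by_source = {"seed": 0, "expanded": 0}
    for e in lexicon:
        by_category[e.category] += 1
        by_weight[e.weight] += 1
        by_source[e.source] += 1
    return {
        "total": len(lexicon),
        "by_category": by_category,
        "by_weight": by_weight,
        "by_source": by_source,
    }


def apply_vote_filter(
    entries: Sequence[LexiconEntry],
    votes: Iterable[VoteRecord],
    quorum: int = 2,
) -> list[LexiconEntry]:
    """Drop every entry whose word drew ``eliminate`` votes from at least
    ``quorum`` distinct coders.

    The default quorum of 2 encodes the two-of-three-coders elimination
    rule.  Entries with no votes are retained; retained entries keep their
    input order.  Votes naming words absent from ``entries`` are ignored
    with a warning.
    """
    if quorum < 1:
        raise ValueError("quorum must be >= 1")
    known = {e.word for e in entries}
    eliminators: dict[str, set[str]] = {}
    for v in votes:
        if v.word not in known:
            logger.warning("vote for unknown word ignored: %r (coder %s)", v.word, v.coder_id)
            continue
        if v.decision == "eliminate":
            eliminators.setdefault(v.word, set()).add(v.coder_id)
    return [e for e in entries if len(eliminators.get(e.word, ())) < quorum]


def merge(seed: SuicideLexicon, accepted_expansions: Sequence[LexiconEntry]) -> SuicideLexicon:
    """Merge reviewed expansion entries into a seed lexicon.

    Words already present in the seed are skipped (the seed entry wins) and
    the skip is logged.  Expansion entries must carry ``source="expanded"``.
    """
    merged = list(seed.entries)
    present = set(seed.words)
    for e in accepted_expansions:
        if e.source != "expanded":
            raise LexiconError(f"expansion entry {e.word!r} must have source='expanded'")
        if e.word in present:
            logger.info("merge: expansion %r collides with seed entry, skipped", e.word)
            continue
        merged.append(e)
        present.add(e.word)
    return SuicideLexicon(entries=merged, version=seed.version)


def _parse_optional_int(token: str, what: str, lineno: int) -> int | None:
    if token == "":
        return None
    try:
        return int(token)
    except ValueError:
        raise LexiconError(f"line {lineno}: {what} is not an integer: {token!r}") from None


def load_lexicon(path: str | Path) -> SuicideLexicon:
    """Read a lexicon from a UTF-8 TSV file.

    Expected header: ``word  category  weight  source  corpus_frequency``
    (tab-separated).  Duplicate words, unknown categories and weights
    outside {1, 2, 3} are rejected with errors naming the offending line.
    """
    path = Path(path)
    entries: list[LexiconEntry] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != LEXICON_COLUMNS:
            raise LexiconError(f"{path}: bad header {header!r}, expected {list(LEXICON_COLUMNS)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(LEXICON_COLUMNS):
                raise LexiconError(
                    f"{path}: line {lineno}: expected {len(LEXICON_COLUMNS)} fields, got {len(parts)}"
                )
            word, category, weight_s, source, freq_s = parts
            try:
                weight = int(weight_s)
            except ValueError:
                raise LexiconError(f"{path}: line {lineno}: weight is not an integer: {weight_s!r}") from None
            freq = _parse_optional_int(freq_s, "corpus_frequency", lineno)
            try:
                entries.append(
                    LexiconEntry(word=word, category=category, weight=weight, source=source, corpus_frequency=freq)
                )
            except LexiconError as exc:
                raise LexiconError(f"{path}: line {lineno}: {exc}") from None
    try:
        return SuicideLexicon(entries=entries)
    except LexiconError as exc:
        raise LexiconError(f"{path}: {exc}") from None


def write_lexicon(lexicon: SuicideLexicon, path: str | Path) -> None:
    """Write a lexicon as UTF-8 TSV; ``load_lexicon`` round-trips it losslessly."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(LEXICON_COLUMNS) + "\n")
        for e in lexicon:
            freq = "" if e.corpus_frequency is None else str(e.corpus_frequency)
            fh.write(f"{e.word}\t{e.category}\t{e.weight}\t{e.source}\t{freq}\n")


def load_votes(path: str | Path) -> list[VoteRecord]:
    """Read a vote manifest TSV: word, coder_id, decision, proposed_category, proposed_weight."""
    path = Path(path)
    votes: list[VoteRecord] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != VOTE_COLUMNS:
            raise LexiconError(f"{path}: bad header {header!r}, expected {list(VOTE_COLUMNS)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(VOTE_COLUMNS):
                raise LexiconError(
                    f"{path}: line {lineno}: expected {len(VOTE_COLUMNS)} fields, got {len(parts)}"
                )
            word, coder, decision, pcat, pweight_s = parts
            pweight = _parse_optional_int(pweight_s, "proposed_weight", lineno)
            try:
                votes.append(
                    VoteRecord(
                        word=word,
                        coder_id=coder,
                        decision=decision,
                        proposed_category=pcat or None,
                        proposed_weight=pweight,
                    )
                )
            except LexiconError as exc:
                raise LexiconError(f"{path}: line {lineno}: {exc}") from None
    return votes


def write_votes(votes: Sequence[VoteRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(VOTE_COLUMNS) + "\n")
        for v in votes:
            pcat = v.proposed_category or ""
            pw = "" if v.proposed_weight is None else str(v.proposed_weight)
            fh.write(f"{v.word}\t{v.coder_id}\t{v.decision}\t{pcat}\t{pw}\n")
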