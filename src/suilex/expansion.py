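"""Embedding-based lexicon expansion with category/weight inheritance and
vote-based review.

Each lexicon word is looked up in a pre-trained word-embedding space and
its k nearest neighbors by cosine similarity (k = 4 by default) are
proposed as expansion candidates, inheriting the seed word's category and
weight.  Candidates already in the lexicon, or below a corpus-frequency
floor, are skipped.  Proposals then go through the same coder-vote review
as the seed list: a quorum (2 of 3) of eliminate votes rejects a
candidate, and a quorum of identical override votes may retune a
surviving candidate's category or weight.

Embeddings are consumed in word2vec text format (header line
``vocab_size dim``, then one ``word v1 ... vd`` row per word); training
them is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .lexicon import CATEGORIES, LexiconEntry, SuicideLexicon, VoteRecord

logger = logging.getLogger(__name__)

DEFAULT_K = 4
DEFAULT_MIN_CORPUS_FREQ = 5

CANDIDATE_COLUMNS = (
    "seed_word",
    "candidate_word",
    "similarity",
    "inherited_category",
    "inherited_weight",
    "status",
)


class EmbeddingError(ValueError):
    pass


@dataclass(frozen=True)
class ExpansionCandidate:
    """A proposed lexicon addition: a neighbor of ``seed_word`` inheriting
    its category and weight, pending review."""

    seed_word: str
    candidate_word: str
    similarity: float
    inherited_category: str
    inherited_weight: int
    status: str = "proposed"

    def __post_init__(self) -> None:
        if self.candidate_word == self.seed_word:
            raise EmbeddingError("candidate must differ from its seed word")
        if self.inherited_category not in CATEGORIES:
            raise EmbeddingError(f"unknown category {self.inherited_category!r}")
        if self.inherited_weight not in (1, 2, 3):
            raise EmbeddingError(f"weight must be 1, 2 or 3, got {self.inherited_weight!r}")
        if self.status not in ("proposed", "accepted", "rejected"):
            raise EmbeddingError(f"bad status {self.status!r}")


class EmbeddingModel:
    """Dense word vectors with cosine-similarity queries.

    Vectors are L2-normalized at load time (zero vectors are kept as
    zeros), so similarity is a dot product.
    """

    def __init__(self, words: Sequence[str], vectors: np.ndarray) -> None:
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] != len(words):
            raise EmbeddingError("vectors must be a (n_words, dim) matrix")
        if len(set(words)) != len(words):
            raise EmbeddingError("duplicate words in embedding vocabulary")
        self.words: tuple[str, ...] = tuple(words)
        self.index: dict[str, int] = {w: i for i, w in enumerate(self.words)}
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        self._unit = np.divide(vectors, norms, out=np.zeros_like(vectors), where=norms > 0)
        self.dim = vectors.shape[1]

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.index)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def vector(self, word: str) -> np.ndarray:
        return self._unit[self.index[word]].copy()

    def similarity(self, a: str, b: str) -> float:
        return float(self._unit[self.index[a]] @ self._unit[self.index[b]])


def load_embeddings(path: str | Path) -> EmbeddingModel:
    """Read word2vec text format: first line ``vocab_size dim``, then one
    word and its coordinates per line, space-separated."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingError(f"{path}: bad word2vec header {header!r}")
        n, dim = int(header[0]), int(header[1])
        words: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) == 1 and parts[0] == "":
                continue
            if len(parts) != dim + 1:
                raise EmbeddingError(f"{path}: line {lineno}: expected {dim + 1} fields, got {len(parts)}")
            words.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(words) != n:
        raise EmbeddingError(f"{path}: header declares {n} words, file has {len(words)}")
    return EmbeddingModel(words, np.asarray(rows))


def write_embeddings(model: EmbeddingModel, path: str | Path) -> None:
    """Write (the unit-normalized) vectors in word2vec text format."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{len(model.words)} {model.dim}\n")
        for i, w in enumerate(model.words):
            coords = " ".join(repr(float(x)) for x in model._unit[i])
            fh.write(f"{w} {coords}\n")


def nearest_neighbors(model: EmbeddingModel, word: str, k: int) -> list[tuple[str, float]]:
    """The k most cosine-similar in-vocabulary words to ``word``, excluding
    the query itself, in descending similarity; ties break lexicographically.

    An out-of-vocabulary query returns an empty list with a logged notice.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if word not in model:
        logger.info("nearest_neighbors: %r not in vocabulary", word)
        return []
    qi = model.index[word]
    sims = model._unit @ model._unit[qi]
    order = sorted(
        (i for i in range(len(model.words)) if i != qi),
        key=lambda i: (-sims[i], model.words[i]),
    )
    return [(model.words[i], float(sims[i])) for i in order[:k]]


def propose_expansions(
    lexicon: SuicideLexicon,
    model: EmbeddingModel,
    k: int = DEFAULT_K,
    min_corpus_freq: int = DEFAULT_MIN_CORPUS_FREQ,
    corpus_frequencies: dict[str, int] | None = None,
) -> list[ExpansionCandidate]:
    """Propose up to k neighbor candidates per in-vocabulary lexicon word.

    Candidates already in the lexicon are skipped; candidates whose corpus
    frequency (when supplied) falls below ``min_corpus_freq`` are skipped;
    a word proposed by several seeds is kept once under its most similar
    seed (ties to the lexicographically smaller seed).  Output is sorted by
    (seed_word, descending similarity, candidate_word).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_corpus_freq < 0:
        raise ValueError("min_corpus_freq must be >= 0")
    best: dict[str, ExpansionCandidate] = {}
    for entry in lexicon:
        if entry.word not in model:
            continue
        for cand_word, sim in nearest_neighbors(model, entry.word, k):
            if cand_word in lexicon:
                continue
            if corpus_frequencies is not None and corpus_frequencies.get(cand_word, 0) < min_corpus_freq:
                continue
            cand = ExpansionCandidate(
                seed_word=entry.word,
                candidate_word=cand_word,
                similarity=sim,
                inherited_category=entry.category,
                inherited_weight=entry.weight,
            )
            prev = best.get(cand_word)
            if prev is None or (-cand.similarity, cand.seed_word) < (-prev.similarity, prev.seed_word):
                best[cand_word] = cand
    return sorted(best.values(), key=lambda c: (c.seed_word, -c.similarity, c.candidate_word))


def apply_review(
    candidates: Sequence[ExpansionCandidate],
    votes: Iterable[VoteRecord],
    quorum: int = 2,
) -> list[LexiconEntry]:
    """Apply coder votes to expansion candidates.

    A candidate with >= quorum distinct-coder eliminate votes is rejected.
    Among survivors, a category (or weight) override applies iff >= quorum
    coders proposed the identical value; conflicting proposals without a
    quorum keep the inherited value, with the conflict logged.  Accepted
    entries carry ``source="expanded"``.
    """
    if quorum < 1:
        raise ValueError("quorum must be >= 1")
    by_word: dict[str, list[VoteRecord]] = {}
    for v in votes:
        by_word.setdefault(v.word, []).append(v)
    accepted: list[LexiconEntry] = []
    for cand in candidates:
        word_votes = by_word.get(cand.candidate_word, [])
        eliminators = {v.coder_id for v in word_votes if v.decision == "eliminate"}
        if len(eliminators) >= quorum:
            continue
        category = _resolve_override(
            cand.candidate_word,
            "category",
            {v.coder_id: v.proposed_category for v in word_votes if v.proposed_category is not None},
            cand.inherited_category,
            quorum,
        )
        weight = _resolve_override(
            cand.candidate_word,
            "weight",
            {v.coder_id: v.proposed_weight for v in word_votes if v.proposed_weight is not None},
            cand.inherited_weight,
            quorum,
        )
        accepted.append(
            LexiconEntry(word=cand.candidate_word, category=category, weight=weight, source="expanded")
        )
    return accepted


def _resolve_override(word, field_name, proposals_by_coder, inherited, quorum):
    if not proposals_by_coder:
        return inherited
    tally: dict[object, int] = {}
    for value in proposals_by_coder.values():
        tally[value] = tally.get(value, 0) + 1
    value, count = max(tally.items(), key=lambda kv: kv[1])
    if count >= quorum:
        return value
    logger.info("override conflict on %s of %r without quorum; inherited value kept", field_name, word)
    return inherited


# ---------------------------------------------------------- candidate I/O


def write_candidates(candidates: Sequence[ExpansionCandidate], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            fh.write(
                f"{c.seed_word}\t{c.candidate_word}\t{c.similarity!r}\t"
                f"{c.inherited_category}\t{c.inherited_weight}\t{c.status}\n"
            )


def load_candidates(path: str | Path) -> list[ExpansionCandidate]:
    path = Path(path)
    out: list[ExpansionCandidate] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CANDIDATE_COLUMNS:
            raise EmbeddingError(f"{path}: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(CANDIDATE_COLUMNS):
                raise EmbeddingError(f"{path}: line {lineno}: expected {len(CANDIDATE_COLUMNS)} fields")
            seed, cand, sim, cat, weight, status = parts
            out.append(
                ExpansionCandidate(
                    seed_word=seed,
                    candidate_word=cand,
                    similarity=float(sim),
                    inherited_category=cat,
                    inherited_weight=int(weight),
                    status=status,
                )
            )
    return out
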