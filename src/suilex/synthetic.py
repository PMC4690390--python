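"""Seeded generators for every input the pipeline consumes.

The real dictionary word list and microblog corpus are not published, so
this module fabricates structurally faithful stand-ins: a lexicon with
the published per-category counts and weight mix, a two-group post corpus
in which high-risk users emit lexicon words at a higher per-token rate
than the comparison group, questionnaire records whose totals track group
membership, expert ratings that are a noisy monotone function of true
per-post lexicon content, and toy embeddings with planted synonym
geometry for exercising the expansion search.

Every generator is a pure function of its spec and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np

from .expansion import EmbeddingModel
from .lexicon import CATEGORIES, LexiconEntry, SuicideLexicon
from .matcher import PostScore
from .risk_profile import Post
from .screening import ITEM_MAX, ITEM_MIN, N_ITEMS, SPSRecord

#: Published per-category word counts of the seed+expanded dictionary
#: (sums to 2,168), in the fixed category order.
DEFAULT_CATEGORY_COUNTS: dict[str, int] = dict(
    zip(CATEGORIES, (586, 88, 403, 48, 188, 183, 36, 72, 83, 182, 47, 72, 180))
)

#: Seed-dictionary weight class sizes: 990 weight-1, 505 weight-2,
#: 367 weight-3 words (sums to 1,862).
SEED_WEIGHT_COUNTS: tuple[int, int, int] = (990, 505, 367)
DEFAULT_WEIGHT_PROPORTIONS: tuple[float, float, float] = tuple(
    c / sum(SEED_WEIGHT_COUNTS) for c in SEED_WEIGHT_COUNTS
)

# Disjoint CJK code-point pools: lexicon words and filler tokens never
# share characters, so no match can straddle a token boundary into filler.
_LEXICON_CP_RANGE = (0x4E00, 0x6700)
_FILLER_CP_RANGE = (0x6700, 0x9FFF)
_ASCII_LEXICON = "abcdefghijklm"
_ASCII_FILLER = "nopqrstuvwxyz"


class SyntheticError(RuntimeError):
    pass


def _random_words(
    rng: np.random.Generator,
    n: int,
    style: str,
    pool: str,
    taken: set[str],
    min_len: int = 2,
    max_len: int = 4,
) -> list[str]:
    if style == "cjk":
        lo, hi = _LEXICON_CP_RANGE if pool == "lexicon" else _FILLER_CP_RANGE
        alphabet = None
    elif style == "ascii":
        alphabet = _ASCII_LEXICON if pool == "lexicon" else _ASCII_FILLER
    else:
        raise ValueError(f"vocabulary_style must be 'cjk' or 'ascii', got {style!r}")
    words: list[str] = []
    attempts = 0
    while len(words) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise SyntheticError("could not generate enough unique words; widen length range")
        length = int(rng.integers(min_len, max_len + 1))
        if style == "cjk":
            w = "".join(chr(int(c)) for c in rng.integers(lo, hi, size=length))
        else:
            w = "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), size=length))
        if w in taken:
            continue
        taken.add(w)
        words.append(w)
    return words


def scaled_category_counts(total: int, reference: Mapping[str, int] | None = None) -> dict[str, int]:
    """Scale the reference per-category counts to a new total by
    largest-remainder apportionment (counts sum exactly to ``total``)."""
    if reference is None:
        reference = DEFAULT_CATEGORY_COUNTS
    ref = np.asarray([reference.get(c, 0) for c in CATEGORIES], dtype=float)
    counts = _largest_remainder(total * ref / ref.sum(), total)
    return dict(zip(CATEGORIES, (int(k) for k in counts)))


def make_lexicon(
    category_counts: Mapping[str, int] | None = None,
    weight_proportions: Sequence[float] = DEFAULT_WEIGHT_PROPORTIONS,
    vocabulary_style: str = "cjk",
    seed: int = 0,
    source: str = "seed",
    weight_counts: Sequence[int] | None = None,
) -> SuicideLexicon:
    """Generate a synthetic lexicon with the given category counts and
    weight mix.

    Defaults reproduce the published dictionary shape: category counts
    summing to 2,168 and the 990/505/367 weight proportions.  Weights are
    assigned by deterministic largest-remainder apportionment, so the
    global weight mix tracks the proportions exactly up to rounding;
    passing explicit ``weight_counts`` (summing to the lexicon size)
    enforces the weight classes exactly — e.g. the 990/505/367 seed mix
    over a 1,862-word lexicon.  Deterministic given ``seed``.
    """
    if category_counts is None:
        category_counts = DEFAULT_CATEGORY_COUNTS
    total = int(sum(int(category_counts.get(c, 0)) for c in CATEGORIES))
    if weight_counts is not None:
        weight_counts = tuple(int(k) for k in weight_counts)
        if len(weight_counts) != 3 or sum(weight_counts) != total:
            raise ValueError("weight_counts must be 3 values summing to the lexicon size")
        weights = [w for w, k in zip((1, 2, 3), weight_counts) for _ in range(k)]
    else:
        props = np.asarray(weight_proportions, dtype=float)
        if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError("weight_proportions must be 3 non-negative values summing to 1")
        per_weight = _largest_remainder(props * total, total)
        weights = [w for w, k in zip((1, 2, 3), per_weight) for _ in range(int(k))]
    rng = np.random.default_rng(seed)
    weights = [int(w) for w in rng.permutation(weights)]  # decouple weight from category
    taken: set[str] = set()
    entries: list[LexiconEntry] = []
    pos = 0
    for cat in CATEGORIES:
        n = int(category_counts.get(cat, 0))
        if n < 0:
            raise ValueError(f"negative count for {cat}")
        words = _random_words(rng, n, vocabulary_style, "lexicon", taken)
        for word in words:
            entries.append(
                LexiconEntry(word=word, category=cat, weight=weights[pos], source=source)
            )
            pos += 1
    return SuicideLexicon(entries=entries, version=f"synthetic-{seed}")


def _largest_remainder(exact: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative quotas to integers summing exactly to total."""
    base = np.floor(exact).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return base


@dataclass(frozen=True)
class CorpusSpec:
    """Shape of a two-group synthetic post corpus.

    ``p_risk_word_high`` / ``p_risk_word_low`` are per-token probabilities
    that a token is drawn from the lexicon rather than from filler
    vocabulary; the planted group effect the downstream recovery tests
    look for lives entirely in this difference.
    """

    n_users_high: int = 60
    n_users_non_high: int = 60
    posts_per_user: int | tuple[int, int] = 50
    tokens_per_post: tuple[int, int] = (5, 40)
    p_risk_word_high: float = 0.08
    p_risk_word_low: float = 0.02
    anchor: datetime = datetime(2014, 7, 13)
    time_span_days: float = 90.0
    n_filler_words: int = 500
    vocabulary_style: str = "cjk"

    def __post_init__(self) -> None:
        if not (0 <= self.p_risk_word_low <= self.p_risk_word_high <= 1):
            raise ValueError("need 0 <= p_low <= p_high <= 1")
        if min(self.n_users_high, self.n_users_non_high) < 0:
            raise ValueError("user counts must be >= 0")


def make_corpus(
    lexicon: SuicideLexicon,
    spec: CorpusSpec = CorpusSpec(),
    seed: int = 0,
) -> tuple[list[Post], "GroundTruth"]:
    """Generate posts for two user groups with planted lexicon-word rates.

    Each token is a uniformly chosen lexicon word with the user's group
    probability, otherwise a filler token guaranteed disjoint from the
    lexicon.  CJK-style posts concatenate tokens without separators
    (unsegmented text); ASCII-style posts are space-separated.  Timestamps
    are uniform over (anchor - time_span, anchor].  Deterministic given
    ``seed``.  Returns the posts and a per-user ground-truth table.
    """
    rng = np.random.default_rng(seed)
    lex_words = [e.word for e in lexicon]
    taken = {e.word for e in lexicon}
    fillers = _random_words(rng, spec.n_filler_words, spec.vocabulary_style, "filler", taken)
    sep = "" if spec.vocabulary_style == "cjk" else " "
    posts: list[Post] = []
    rows: list[dict] = []
    groups = [("high", spec.n_users_high, spec.p_risk_word_high), ("non_high", spec.n_users_non_high, spec.p_risk_word_low)]
    uid_width = len(str(spec.n_users_high + spec.n_users_non_high))
    counter = 0
    for group, n_users, p in groups:
        for _ in range(n_users):
            counter += 1
            uid = f"u{counter:0{uid_width}d}"
            rows.append({"user_id": uid, "group": group, "emission_p": p})
            if isinstance(spec.posts_per_user, tuple):
                n_posts = int(rng.integers(spec.posts_per_user[0], spec.posts_per_user[1] + 1))
            else:
                n_posts = spec.posts_per_user
            for _ in range(n_posts):
                n_tok = int(rng.integers(spec.tokens_per_post[0], spec.tokens_per_post[1] + 1))
                risky = rng.random(n_tok) < p
                tokens = [
                    lex_words[int(rng.integers(0, len(lex_words)))] if r and lex_words
                    else fillers[int(rng.integers(0, len(fillers)))]
                    for r in risky
                ]
                offset = float(rng.uniform(0.0, spec.time_span_days))
                ts = spec.anchor - timedelta(days=offset)
                posts.append(Post(user_id=uid, timestamp=ts, text=sep.join(tokens)))
    return posts, GroundTruth(rows)


class GroundTruth:
    """Per-user truth emitted alongside a synthetic corpus: group label and
    token-level lexicon-word emission probability."""

    def __init__(self, rows: list[dict]) -> None:
        self.rows = rows
        self._by_user = {r["user_id"]: r for r in rows}

    def group(self, user_id: str) -> str:
        return self._by_user[user_id]["group"]

    def emission_p(self, user_id: str) -> float:
        return self._by_user[user_id]["emission_p"]

    @property
    def user_ids(self) -> list[str]:
        return [r["user_id"] for r in self.rows]

    def write_tsv(self, path) -> None:
        from pathlib import Path

        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("user_id\tgroup\temission_p\n")
            for r in self.rows:
                fh.write(f"{r['user_id']}\t{r['group']}\t{r['emission_p']!r}\n")


# Reference questionnaire-total distribution: pooled mean 69.35, SD 11.66,
# high/non-high split at 69.35 + 11.66 = 81.01.  The default group means are
# the conditional means of N(69.35, 11.66^2) above/below that cutoff
# (mean + sd*phi(1)/(1-Phi(1)) and mean - sd*phi(1)/Phi(1)), so a cohort
# with ~15.9% high users pools back to mean ~69.35.
DEFAULT_SPS_MEAN_HIGH = 87.13
DEFAULT_SPS_MEAN_LOW = 66.0
DEFAULT_SPS_SD = 11.66


def make_sps(
    ground_truth: GroundTruth,
    mean_high: float = DEFAULT_SPS_MEAN_HIGH,
    mean_low: float = DEFAULT_SPS_MEAN_LOW,
    sd: float = DEFAULT_SPS_SD,
    seed: int = 0,
) -> list[SPSRecord]:
    """Questionnaire records whose totals are normal draws around the
    user's group mean, clipped to the attainable 36–144 range.

    The target total is spread over the 36 items deterministically (all
    items start at 1; the remainder is distributed one point at a time,
    capped at 4 per item), so items are valid and totals exact after
    clipping and rounding.
    """
    rng = np.random.default_rng(seed)
    records: list[SPSRecord] = []
    lo, hi = N_ITEMS * ITEM_MIN, N_ITEMS * ITEM_MAX
    for uid in ground_truth.user_ids:
        mean = mean_high if ground_truth.group(uid) == "high" else mean_low
        total = int(np.clip(round(mean + sd * rng.standard_normal()), lo, hi))
        records.append(SPSRecord(user_id=uid, items=_items_for_total(total)))
    return records


def _items_for_total(total: int) -> tuple[int, ...]:
    items = [ITEM_MIN] * N_ITEMS
    remainder = total - N_ITEMS * ITEM_MIN
    i = 0
    while remainder > 0:
        if items[i] < ITEM_MAX:
            items[i] += 1
            remainder -= 1
        i = (i + 1) % N_ITEMS
    return tuple(items)


@dataclass(frozen=True)
class ExpertRatingSpec:
    """Noise and aggregation settings for simulated expert raters.

    Each of three simulated coders maps a post's true lexicon content
    through a linear ramp onto the 1–7 scale, adds Gaussian noise of
    ``noise_sd``, and is clipped to the scale; the final rating averages
    the coders.  ``aggregation`` selects how per-category ratings combine
    into an overall rating (sum or mean over categories).
    """

    noise_sd: float = 0.5
    aggregation: str = "sum"
    n_coders: int = 3
    slope: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError("aggregation must be 'sum' or 'mean'")


def make_expert_ratings(
    post_scores: Sequence[PostScore],
    spec: ExpertRatingSpec = ExpertRatingSpec(),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated expert ratings for a sequence of scored posts.

    Returns ``(per_post_overall, per_post_by_category)`` where
    ``per_post_by_category`` has one column per lexicon category on the
    1–7 scale and ``per_post_overall`` aggregates categories per ``spec``.
    In the noiseless limit ratings are an exact linear-then-clip function
    of the true category content, so they correlate perfectly with post
    scores wherever no clipping occurs.
    """
    rng = np.random.default_rng(seed)
    n = len(post_scores)
    cat_index = {c: j for j, c in enumerate(CATEGORIES)}
    # weighted per-category content: heavier words read as stronger signal,
    # and the noiseless overall rating is then linear in the post score
    content = np.zeros((n, len(CATEGORIES)))
    for i, s in enumerate(post_scores):
        for occ in s.occurrences:
            content[i, cat_index[occ.category]] += occ.weight
    base = 1.0 + spec.slope * content
    coder_ratings = np.empty((spec.n_coders, n, len(CATEGORIES)))
    for c in range(spec.n_coders):
        noisy = base + rng.normal(0.0, spec.noise_sd, size=base.shape) if spec.noise_sd > 0 else base
        coder_ratings[c] = np.clip(noisy, 1.0, 7.0)
    by_category = coder_ratings.mean(axis=0)
    overall = by_category.sum(axis=1) if spec.aggregation == "sum" else by_category.mean(axis=1)
    return overall, by_category


def make_embeddings(
    lexicon: SuicideLexicon,
    synonyms_per_word: int = 4,
    n_distractors: int = 500,
    dim: int = 50,
    seed: int = 0,
    perturbation: float = 0.05,
    max_retries: int = 20,
) -> tuple[EmbeddingModel, dict[str, list[str]]]:
    """Toy embedding space with planted synonym geometry.

    Each lexicon word receives a random unit vector; each of its planted
    synonyms is a small perturbation of that vector; distractors are
    independent random unit vectors.  Generation verifies that every
    synonym is strictly more similar to its seed than any distractor or
    other lexicon word is, retrying with a smaller perturbation if the
    check fails.  Returns the model and the seed-word -> synonyms map.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)
    style = "ascii" if all(ord(c) < 128 for e in lexicon for c in e.word) and len(lexicon) else "cjk"
    taken = {e.word for e in lexicon}
    syn_words = _random_words(rng, synonyms_per_word * len(lexicon), style, "lexicon", taken)
    distractor_words = _random_words(rng, n_distractors, style, "filler", taken)

    eps = perturbation
    for attempt in range(max_retries):
        words: list[str] = []
        vecs: list[np.ndarray] = []
        synonyms: dict[str, list[str]] = {}
        it = iter(syn_words)
        for e in lexicon:
            v = _unit(rng.standard_normal(dim))
            words.append(e.word)
            vecs.append(v)
            mine = [next(it) for _ in range(synonyms_per_word)]
            synonyms[e.word] = mine
            for s in mine:
                words.append(s)
                vecs.append(_unit(v + eps * rng.standard_normal(dim)))
        for w in distractor_words:
            words.append(w)
            vecs.append(_unit(rng.standard_normal(dim)))
        model = EmbeddingModel(words, np.asarray(vecs))
        if _synonym_margin_ok(model, synonyms):
            return model, synonyms
        eps /= 2.0
    raise SyntheticError(
        "could not plant synonym geometry; raise dim or lower the perturbation"
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise SyntheticError("degenerate zero vector drawn")
    return v / n


def _synonym_margin_ok(model: EmbeddingModel, synonyms: dict[str, list[str]]) -> bool:
    for seed_word, syns in synonyms.items():
        if not syns:
            continue
        others = [w for w in model.words if w != seed_word and w not in syns]
        worst_syn = min(model.similarity(seed_word, s) for s in syns)
        if others:
            best_other = max(model.similarity(seed_word, o) for o in others)
            if worst_syn <= best_other:
                return False
    return True
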