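"""User-level aggregation: observation windows, risk levels, category
frequencies and classifier feature vectors.

A user's risk level over an observation window is the proportion of their
posts in that window whose dictionary score flags them as risky.  Windows
are fixed-length periods ending at an anchor instant (study start or
questionnaire date): 1 week = 7 days, 1 month = 30, 2 months = 60,
3 months = 90, with the half-open interval (anchor - length, anchor] so a
post at the anchor itself is included and adjacent windows never double
count.

Feature vectors for classification hold, per lexicon category, the ratio
of matched occurrences to the user's total token count across their
windowed posts.  Tokenization is an injected contract — any callable
mapping text to a deterministic token list works; a whitespace tokenizer
and a character tokenizer (every non-space character is a token, the
dependency-free choice for unsegmented text) are provided.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .lexicon import CATEGORIES
from .matcher import Matcher, PostScore, score_post

logger = logging.getLogger(__name__)

Tokenizer = Callable[[str], Sequence[str]]

#: Named window lengths in days.
WINDOW_DAYS: dict[str, int] = {"1_week": 7, "1_month": 30, "2_months": 60, "3_months": 90}


class ProfileError(ValueError):
    pass


def whitespace_tokenizer(text: str) -> list[str]:
    return text.split()


def character_tokenizer(text: str) -> list[str]:
    """One token per non-whitespace character; suits unsegmented CJK text."""
    return [ch for ch in text if not ch.isspace()]


@dataclass(frozen=True)
class Post:
    user_id: str
    timestamp: datetime
    text: str

    def __post_init__(self) -> None:
        if not self.user_id:
            raise ProfileError("user_id must be non-empty")


@dataclass(frozen=True)
class ObservationWindow:
    """A period of ``days`` days ending at ``anchor`` (inclusive)."""

    anchor: datetime
    days: float

    def __post_init__(self) -> None:
        if self.days < 0:
            raise ProfileError("window length must be >= 0 days")

    @classmethod
    def named(cls, anchor: datetime, length: str) -> "ObservationWindow":
        if length not in WINDOW_DAYS:
            raise ProfileError(f"unknown window length {length!r}; expected one of {sorted(WINDOW_DAYS)}")
        return cls(anchor=anchor, days=WINDOW_DAYS[length])

    def contains(self, t: datetime) -> bool:
        if self.days == float("inf"):
            return t <= self.anchor
        if self.days == 0:  # degenerate window: the anchor instant itself
            return t == self.anchor
        return self.anchor - timedelta(days=self.days) < t <= self.anchor


@dataclass(frozen=True)
class UserRiskProfile:
    """Windowed per-user risk: risk_level = n_risky / n_posts."""

    user_id: str
    window: ObservationWindow
    n_posts: int
    n_risky: int
    risk_level: float


@dataclass(frozen=True)
class FeatureVector:
    """Per-user category-ratio vector, ordered by the fixed category
    enumeration; denominator is the total token count."""

    user_id: str
    values: tuple[float, ...]
    denominator: int


def parse_timestamp(value: str) -> datetime:
    try:
        return datetime.fromisoformat(value)
    except ValueError:
        raise ProfileError(f"unparseable ISO-8601 timestamp: {value!r}") from None


def select_window(posts: Sequence[Post], window: ObservationWindow) -> list[Post]:
    """Posts with timestamp in (anchor - length, anchor], original order kept."""
    return [p for p in posts if window.contains(p.timestamp)]


def user_risk_level(user_id: str, scored_posts: Sequence[PostScore], window: ObservationWindow) -> UserRiskProfile:
    """Proportion of risky posts among a user's windowed, scored posts.

    Raises :class:`ProfileError` when the user has no posts in the window
    (the profile is undefined; callers exclude and log such users).
    """
    n = len(scored_posts)
    if n == 0:
        raise ProfileError(f"user {user_id!r} has no posts in the window; risk level undefined")
    n_risky = sum(1 for s in scored_posts if s.is_risky)
    return UserRiskProfile(
        user_id=user_id, window=window, n_posts=n, n_risky=n_risky, risk_level=n_risky / n
    )


def category_frequencies(scored_posts: Iterable[PostScore]) -> tuple[dict[str, int], int]:
    """Aggregate per-category occurrence counts across posts.

    Returns ``(per_category, overall)`` where overall equals the sum of the
    per-category counts.
    """
    counts = {c: 0 for c in CATEGORIES}
    for s in scored_posts:
        for cat, k in s.category_counts.items():
            counts[cat] = counts.get(cat, 0) + k
    return counts, sum(counts.values())


def extract_features(
    user_id: str,
    posts: Sequence[Post],
    matcher: Matcher,
    tokenizer: Tokenizer = character_tokenizer,
) -> FeatureVector:
    """Category-ratio feature vector for one user's posts.

    Element *c* is the number of matched occurrences in category *c* across
    the posts, divided by the total token count across the same posts.
    Raises :class:`ProfileError` on zero total tokens.
    """
    n_tokens = 0
    counts = {c: 0 for c in CATEGORIES}
    for p in posts:
        n_tokens += len(tokenizer(p.text))
        for m in matcher.find_matches(p.text):
            counts[m.category] += 1
    if n_tokens == 0:
        raise ProfileError(f"user {user_id!r} has zero tokens; feature vector undefined")
    values = tuple(counts[c] / n_tokens for c in CATEGORIES)
    return FeatureVector(user_id=user_id, values=values, denominator=n_tokens)


def profile_users(
    posts: Sequence[Post],
    matcher: Matcher,
    window: ObservationWindow,
    threshold: int = 3,
) -> tuple[list[UserRiskProfile], list[str]]:
    """Score and window all posts, grouped by user.

    Returns the profiles for users with at least one post in the window and
    the (logged) list of excluded user ids.
    """
    by_user: dict[str, list[Post]] = {}
    for p in posts:
        by_user.setdefault(p.user_id, []).append(p)
    profiles: list[UserRiskProfile] = []
    excluded: list[str] = []
    for uid in sorted(by_user):
        windowed = select_window(by_user[uid], window)
        scored = [score_post(matcher.find_matches(p.text), threshold=threshold) for p in windowed]
        try:
            profiles.append(user_risk_level(uid, scored, window))
        except ProfileError:
            logger.info("user %s excluded: no posts in window", uid)
            excluded.append(uid)
    return profiles, excluded


def feature_matrix(
    posts: Sequence[Post],
    matcher: Matcher,
    window: ObservationWindow | None = None,
    tokenizer: Tokenizer = character_tokenizer,
) -> tuple[list[FeatureVector], list[str]]:
    """Feature vectors for all users, window-scoped by default.

    Passing ``window=None`` uses every post of each user.  Users with no
    tokens in scope are excluded and reported.
    """
    by_user: dict[str, list[Post]] = {}
    for p in posts:
        by_user.setdefault(p.user_id, []).append(p)
    vectors: list[FeatureVector] = []
    excluded: list[str] = []
    for uid in sorted(by_user):
        scoped = by_user[uid] if window is None else select_window(by_user[uid], window)
        try:
            vectors.append(extract_features(uid, scoped, matcher, tokenizer))
        except ProfileError:
            logger.info("user %s excluded from features: no tokens in scope", uid)
            excluded.append(uid)
    return vectors, excluded


# ---------------------------------------------------------------- post I/O


def load_posts(path: str | Path) -> list[Post]:
    """Read posts from JSONL or CSV with fields user_id, timestamp, text."""
    path = Path(path)
    posts: list[Post] = []
    if path.suffix.lower() == ".csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):
                posts.append(_post_from_record(row, f"{path}:{i}"))
    else:
        with path.open("r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                posts.append(_post_from_record(json.loads(line), f"{path}:{i}"))
    return posts


def _post_from_record(rec: Mapping[str, str], where: str) -> Post:
    try:
        return Post(
            user_id=str(rec["user_id"]),
            timestamp=parse_timestamp(str(rec["timestamp"])),
            text=str(rec["text"]),
        )
    except (KeyError, ProfileError) as exc:
        raise ProfileError(f"{where}: bad post record: {exc}") from None


def write_posts(posts: Sequence[Post], path: str | Path) -> None:
    """Write posts as JSONL (user_id, ISO timestamp, text)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for p in posts:
            fh.write(
                json.dumps(
                    {"user_id": p.user_id, "timestamp": p.timestamp.isoformat(), "text": p.text},
                    ensure_ascii=False,
                )
                + "\n"
            )
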