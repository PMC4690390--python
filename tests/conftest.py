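import random

import pytest
from hypothesis import HealthCheck, settings

from suilex.lexicon import CATEGORIES, LexiconEntry, SuicideLexicon

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def brute_force_matches(word_table, text, mode):
    """Independent matcher oracle: enumerate every substring of ``text``
    against the word table and apply the mode's rule directly.

    ``word_table`` maps word -> (category, weight).  Returns (word, start,
    end) triples sorted by start, ties by descending length.
    """
    n = len(text)
    all_occ = [
        (text[i:j], i, j)
        for i in range(n)
        for j in range(i + 1, n + 1)
        if text[i:j] in word_table
    ]
    if mode == "all_occurrences":
        return sorted(all_occ, key=lambda t: (t[1], -(t[2] - t[1])))
    # leftmost_longest: walk left to right, take the longest match at each
    # position, resume after its end
    by_start = {}
    for w, i, j in all_occ:
        if i not in by_start or j > by_start[i][2]:
            by_start[i] = (w, i, j)
    out = []
    i = 0
    while i < n:
        if i in by_start:
            out.append(by_start[i])
            i = by_start[i][2]
        else:
            i += 1
    return out


def random_cjk_lexicon(rng: random.Random, n_words: int, min_len=1, max_len=3) -> SuicideLexicon:
    """Small random lexicon over a narrow CJK alphabet (dense matches)."""
    alphabet = [chr(c) for c in range(0x4E00, 0x4E10)]
    words = set()
    while len(words) < n_words:
        length = rng.randint(min_len, max_len)
        words.add("".join(rng.choice(alphabet) for _ in range(length)))
    entries = [
        LexiconEntry(
            word=w,
            category=CATEGORIES[i % len(CATEGORIES)],
            weight=1 + i % 3,
        )
        for i, w in enumerate(sorted(words))
    ]
    return SuicideLexicon(entries=entries)


@pytest.fixture
def tiny_lexicon() -> SuicideLexicon:
    """Hand-built lexicon with a nested word pair (死 inside 想死)."""
    return SuicideLexicon(
        entries=[
            LexiconEntry(word="想死", category="suicide_ideation", weight=3),
            LexiconEntry(word="死", category="suicide_ideation", weight=2),
            LexiconEntry(word="绝望", category="hopeless", weight=2),
            LexiconEntry(word="压力", category="stress", weight=1),
        ]
    )
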