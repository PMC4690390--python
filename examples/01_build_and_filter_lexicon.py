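"""Build a weighted risk lexicon, apply coder elimination votes, and summarize.

A lexicon entry is a (word, category, weight) triple: 13 risk categories,
weights 1 (light) to 3 (heavy).  A word is dropped when at least 2 coders
vote to eliminate it.
"""

from suilex import VoteRecord, apply_vote_filter, summarize
from suilex.lexicon import SuicideLexicon
from suilex import synthetic as syn

# a synthetic lexicon with the published shape: 13 category counts summing
# to 2,168 words
lexicon = syn.make_lexicon(seed=7)
s = summarize(lexicon)
print(f"lexicon size: {s['total']} words")
print(f"weight mix:   {s['by_weight']}")
print(f"largest category: suicide_ideation = {s['by_category']['suicide_ideation']} words")

# three coders review two words; the 2-of-3 rule eliminates the first
w1, w2 = lexicon.entries[0].word, lexicon.entries[1].word
votes = [
    VoteRecord(word=w1, coder_id="c1", decision="eliminate"),
    VoteRecord(word=w1, coder_id="c2", decision="eliminate"),
    VoteRecord(word=w1, coder_id="c3", decision="keep"),
    VoteRecord(word=w2, coder_id="c1", decision="eliminate"),
]
retained = apply_vote_filter(lexicon.entries, votes)
print(f"after review: {len(retained)} of {len(lexicon)} words retained "
      f"({w1!r} eliminated by 2 votes, {w2!r} kept with only 1)")
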