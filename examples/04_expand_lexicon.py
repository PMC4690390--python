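"""Expand a lexicon from word embeddings, review the candidates, merge.

Each lexicon word proposes its 4 nearest neighbors by cosine similarity;
candidates inherit the seed word's category and weight, then face the
same 2-of-3 elimination vote as seed words.  Here the embedding space is
synthetic, with 2 planted synonyms per word, so proposal recovers exactly
the planted neighbors.
"""

from suilex import VoteRecord, apply_review, merge, propose_expansions
from suilex.lexicon import CATEGORIES
from suilex import synthetic as syn

lexicon = syn.make_lexicon(category_counts={c: 2 for c in CATEGORIES}, seed=9)
model, planted = syn.make_embeddings(lexicon, synonyms_per_word=2,
                                     n_distractors=100, dim=24, seed=9)

candidates = propose_expansions(lexicon, model, k=2, min_corpus_freq=0)
planted_words = {s for v in planted.values() for s in v}
print(f"proposed {len(candidates)} candidates; "
      f"{len({c.candidate_word for c in candidates} & planted_words)} are planted synonyms")

# reviewers eliminate one candidate and retune another's inherited weight
first = candidates[0]
second = next(c for c in candidates if c.inherited_weight != 2 and c is not first)
votes = [
    VoteRecord(word=first.candidate_word, coder_id="c1", decision="eliminate"),
    VoteRecord(word=first.candidate_word, coder_id="c2", decision="eliminate"),
    VoteRecord(word=second.candidate_word, coder_id="c1", decision="keep", proposed_weight=2),
    VoteRecord(word=second.candidate_word, coder_id="c2", decision="keep", proposed_weight=2),
]
accepted = apply_review(candidates, votes)
expanded = merge(lexicon, accepted)
retuned = next(e for e in accepted if e.word == second.candidate_word)
print(f"accepted {len(accepted)} after review (1 eliminated); "
      f"{retuned.word!r} weight retuned {second.inherited_weight} -> {retuned.weight}")
print(f"merged lexicon: {len(lexicon)} + {len(accepted)} = {len(expanded)} words")
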