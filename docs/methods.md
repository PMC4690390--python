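# Methods

## The measurement model

`suilex` operationalizes suicide-risk screening on microblog text as
closed-vocabulary measurement.  The instrument is a weighted lexicon
*W* = {(*wᵢ*, *cᵢ*, *xᵢ*)}, *i* = 1…*m*: each word belongs to exactly one
of 13 risk categories and carries an expert-assigned sensitivity weight
*x* ∈ {1, 2, 3}.  Three statistics are derived from it:

1. **Post score.** All lexicon-word occurrences in a post are found and
   their weights summed; a post with total ≥ 3 is flagged as expressing
   suicide risk.  The threshold means one heavy word, one medium word
   plus one light word, or three light words suffice.
2. **User risk level.** Within an observation window ending at an anchor
   date, the user's risk level is the proportion of their posts flagged
   risky — a number in [0, 1].
3. **Category-ratio features.** Per user, a 13-vector whose element for
   category *c* is the count of matched occurrences in *c* divided by the
   user's total token count; these feed a linear SVM that separates
   high- from non-high-risk questionnaire groups.

The approach deliberately ignores context: a word counts wherever it
appears.  That is the model's central limitation (negation, quotation and
sarcasm are all miscounted) and the reason the lexicon's vote-based
curation and weighting matter.

## Matching in unsegmented text

Chinese microblog text has no word delimiters, so matching is a
character-level scan, not a segmentation pipeline.  Two modes:

- `leftmost_longest` (default): scan left to right, at each position take
  the longest lexicon word starting there, resume after its end.
  Occurrences never overlap; a nested word (死 inside 想死) is counted
  once.  This avoids double-counting and makes the post score a sum over
  disjoint text spans.
- `all_occurrences`: every substring equal to a lexicon word is emitted,
  overlaps included — the convention of LIWC-style word-count tools.
  Kept as an explicit mode because either convention is defensible; all
  reported defaults use leftmost-longest.

Text and lexicon words are NFC-normalized; cased (Latin) characters
match case-insensitively, CJK matches exactly.  Lowercasing is applied
per character and skipped for the rare characters whose lowercase
expands, so offsets stay one-to-one.  Both modes are verified, property-
style, against a brute-force oracle that enumerates every substring and
applies the mode's rule.

Occurrence counting is frequency-weighted (every occurrence counts); a
`unique_words` option counts each distinct word once for sensitivity
analysis.

## Windows and user aggregation

Named windows are fixed day counts — 1 week = 7 days, 1 month = 30,
2 months = 60, 3 months = 90 — over the half-open interval
(anchor − L, anchor]: a post at the anchor instant is included, a post
exactly L days before it is not, and adjacent windows never double-count.
Calendar-phrase windows were fixed to day counts for reproducibility.  A
zero-length window degenerates to the anchor instant itself.

Users with no posts (for risk levels) or no tokens (for features) in a
window are excluded from that window's analysis and reported, since both
statistics are undefined ratios there.

The feature denominator is a token count under an injected tokenizer
contract: any deterministic text → token-list callable works.  Two are
shipped — a whitespace tokenizer for segmented text and a character
tokenizer (every non-space character) that needs no segmenter and is the
default for unsegmented text.  Feature vectors are invariant under post
duplication and post order, which the tests assert.  Features may be
computed window-scoped (default) or over all of a user's posts.

## Lexicon curation and expansion

Elimination is by coder vote: a word is dropped when at least `quorum`
(default 2, matching a 2-of-3 panel) distinct coders vote to eliminate
it.  Votes on unknown words are ignored with a warning; the filter is
monotone in eliminate votes.

Expansion searches a word-embedding space (word2vec text format; training
embeddings is out of scope) for each lexicon word's *k* = 4 most
cosine-similar neighbors.  Candidates inherit the seed's category and
weight, skip words already in the lexicon and words below a corpus-
frequency floor (`min_corpus_freq`, default 5 — the curation step drops
low-frequency words without a published cutoff, so it is configurable),
and a word proposed by several seeds is kept once under its most similar
seed.  Ties in similarity break lexicographically so output is
reproducible.  Reviewer votes then reject candidates by the same quorum
rule, and a quorum of identical override votes may retune a survivor's
category or weight; conflicting proposals without quorum keep the
inherited value, logged.  Merging keeps the seed entry on any word
collision — curation never silently replaces a seed word.

## Screening and evaluation

Questionnaire totals sum 36 items scored 1–4 (range 36–144).  The
high-risk cutoff is the sample mean plus the sample (n−1) standard
deviation — the reference cohort's 69.35 + 11.66 = 81.01 — and
membership in the high group requires a total strictly greater than the
cutoff.

The classifier is a linear SVM (C = 1) on features standardized within
the training fold, seeded.  No kernel or regularization search is done:
the comparison of interest is lexicon vs lexicon, not classifier tuning.
Evaluation reports precision, recall and F (harmonic mean; 0 when both
are 0, and zero-denominator precision/recall are reported as 0) for the
high class, as means over stratified 5-fold cross-validation, printed at
2 decimals with half-up rounding as report tables conventionally do.
The chance baseline is the mean cross-validated F after randomly
permuting labels (20 permutations, seeded).

## Synthetic data: what it emulates, what it does not

The real lexicon word list, post corpus and participant data are not
published, so generators fabricate structurally faithful inputs.  All
generators are pure functions of (spec, seed).

- **Lexicon**: random unique words with the published shape — category
  counts (586, 88, 403, 48, 188, 183, 36, 72, 83, 182, 47, 72, 180)
  summing to 2,168, and weight classes 990/505/367 for the 1,862-word
  seed subset (exact via `weight_counts`, otherwise largest-remainder
  apportionment of the proportions).  Weights are decoupled from
  categories by a seeded shuffle.  Words are drawn from a CJK code-point
  block by default (exercising multi-byte matching) with an ASCII mode
  for readable fixtures.
- **Corpus**: two user groups; each token is a lexicon word with the
  group's emission probability (defaults 0.08 high / 0.02 non-high),
  else a filler token.  Lexicon and filler vocabularies use disjoint
  code-point pools, so no match can straddle a token boundary — planted
  emissions and matched occurrences coincide, which the binomial rate
  check exploits.  CJK posts concatenate tokens unseparated (unsegmented
  style); ASCII posts are space-separated.  Posts default to 5–40 tokens
  (microblog scale), 50 posts per user, timestamps uniform over the 90
  days before the anchor.
- **Questionnaire records**: totals drawn normally around group means,
  clipped to [36, 144], and spread deterministically over items.  The
  default means (87.13 high, 66.0 non-high) are the conditional means of
  the reference distribution N(69.35, 11.66²) above/below its
  mean + 1 SD cutoff, so a cohort with the implied ≈ 16% high share
  pools back to the reference mean.
- **Expert ratings**: three simulated coders each map a post's weighted
  per-category content through a linear ramp (1 + 0.5 · content) onto
  the 1–7 scale, add Gaussian noise (default SD 0.5, a moderately
  reliable rater), clip, and are averaged.  In the noiseless limit the
  overall rating is exactly linear in the post score, so the convergent-
  validity correlation is 1 where scores vary and degrades monotonically
  with noise — the property the validation tests check.
- **Embeddings**: each lexicon word gets a random unit vector; planted
  synonyms are small perturbations of it; distractors are independent
  unit vectors.  Generation verifies the margin (every synonym strictly
  closer to its seed than any other word) and retries with a halved
  perturbation on failure.

Passing tests on this data show that the pipeline recovers exactly the
structure the generators plant — token-level emission differences,
synonym geometry, group-correlated questionnaire totals.  They do not
show that the method works on real language: synthetic posts have no
syntax, no context effects, no topic drift, and no innovative spellings,
which are precisely the hard parts of real microblog text.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen to
make every stochastic check stable under its seed: the signal-recovery
corpus uses 60 users per group × 50 posts (≈ 6,000 posts), the expansion
recovery uses 50 seed words × 4 synonyms against 500 distractors in 50
dimensions, matcher/oracle agreement uses 20 random texts per length
1–50 plus 1,000 texts of 200 characters, and the permutation null uses
20 permutations.  Tie-breaks are deterministic throughout (lexicographic
for equal similarities, descending length for equal match starts).
Normalization collisions between lexicon words (two words identical
after NFC + lowercasing) resolve to the higher-weight entry.  Degenerate
inputs — empty lexicons, zero-variance correlation inputs, single-class
training sets, zero-post users — raise typed errors rather than
returning conventional values, except precision/recall, whose
zero-denominator convention (0) is itself part of the reported metric.
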