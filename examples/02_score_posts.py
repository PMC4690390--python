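"""Match lexicon words in unsegmented posts and flag risky ones.

A post's risk score sums the weights of every matched word; a score of 3
or more flags the post (one heavy word is enough).  The default scan is
leftmost-longest, so 死 nested inside 想死 is not double-counted.
"""

from suilex import build_matcher, score_post
from suilex.lexicon import LexiconEntry, SuicideLexicon

lexicon = SuicideLexicon(entries=[
    LexiconEntry(word="想死", category="suicide_ideation", weight=3),
    LexiconEntry(word="死", category="suicide_ideation", weight=2),
    LexiconEntry(word="绝望", category="hopeless", weight=2),
    LexiconEntry(word="压力", category="stress", weight=1),
])
matcher = build_matcher(lexicon)  # leftmost_longest

for text in ["今天想死了", "压力好大好绝望", "天气不错"]:
    occurrences = matcher.find_matches(text)
    score = score_post(occurrences)
    hits = ", ".join(f"{m.word}(w{m.weight})" for m in occurrences) or "none"
    print(f"{text!r}: matches = {hits}; score = {score.total_score}; "
          f"risky = {score.is_risky}")

# 想死 alone scores 3 -> risky; 压力(1) + 绝望(2) also reach 3; the last post scores 0
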