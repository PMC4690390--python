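"""Windowed user risk levels on a synthetic two-group corpus.

A user's risk level in an observation window (here 1 month = the 30 days
up to the anchor) is the proportion of their posts flagged risky.  The
synthetic corpus plants a higher lexicon-word emission rate for the
high-risk group, and the recovered risk levels correlate with that
planted propensity.
"""

from suilex import ObservationWindow, build_matcher, pearson, profile_users
from suilex import synthetic as syn

lexicon = syn.make_lexicon(seed=1)
spec = syn.CorpusSpec(n_users_high=20, n_users_non_high=20, posts_per_user=40)
posts, truth = syn.make_corpus(lexicon, spec, seed=1)

matcher = build_matcher(lexicon)
window = ObservationWindow.named(spec.anchor, "1_month")
profiles, excluded = profile_users(posts, matcher, window)

by_group = {"high": [], "non_high": []}
for p in profiles:
    by_group[truth.group(p.user_id)].append(p.risk_level)
for group, levels in by_group.items():
    print(f"{group:>8}: mean risk level {sum(levels)/len(levels):.3f} over {len(levels)} users")

r = pearson([p.risk_level for p in profiles],
            [truth.emission_p(p.user_id) for p in profiles])
print(f"pearson(risk level, planted emission rate) = {r:.3f}")
# the high group (emission rate 0.08) shows a clearly higher proportion of
# risky posts than the comparison group (0.02), and r is strongly positive
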