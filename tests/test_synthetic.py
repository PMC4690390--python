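"""Synthetic-input generators: determinism, planted rates, disjointness
and the recoverable signal chain."""

import numpy as np
import pytest

from suilex.lexicon import CATEGORIES, SuicideLexicon, summarize
from suilex.matcher import build_matcher, score_post
from suilex.screening import pearson
from suilex import synthetic as syn


class TestMakeLexicon:
    def test_default_shape(self):
        lx = syn.make_lexicon(seed=0)
        s = summarize(lx)
        assert s["total"] == 2168
        assert s["by_category"] == syn.DEFAULT_CATEGORY_COUNTS

    def test_exact_weight_counts(self):
        lx = syn.make_lexicon(
            category_counts=syn.scaled_category_counts(1862),
            weight_counts=syn.SEED_WEIGHT_COUNTS,
            seed=1,
        )
        assert summarize(lx)["by_weight"] == {1: 990, 2: 505, 3: 367}

    def test_all_zero_counts_empty_lexicon(self):
        assert len(syn.make_lexicon(category_counts={c: 0 for c in CATEGORIES})) == 0

    def test_same_seed_identical(self):
        a = syn.make_lexicon(seed=42)
        b = syn.make_lexicon(seed=42)
        assert a.entries == b.entries

    def test_different_seeds_differ(self):
        assert syn.make_lexicon(seed=1).words != syn.make_lexicon(seed=2).words

    def test_ascii_style_words(self):
        lx = syn.make_lexicon(
            category_counts={c: 2 for c in CATEGORIES}, vocabulary_style="ascii", seed=0
        )
        assert all(w.isascii() for w in lx.words)


def small_lexicon(seed=0, n_per_cat=3):
    return syn.make_lexicon(category_counts={c: n_per_cat for c in CATEGORIES}, seed=seed)


class TestMakeCorpus:
    def test_zero_emission_probability_means_no_matches(self):
        lx = small_lexicon()
        spec = syn.CorpusSpec(n_users_high=3, n_users_non_high=3, posts_per_user=5,
                              p_risk_word_high=0.0, p_risk_word_low=0.0)
        posts, _ = syn.make_corpus(lx, spec, seed=0)
        m = build_matcher(lx)
        assert all(m.find_matches(p.text) == [] for p in posts)

    def test_certain_emission_with_heavy_lexicon_makes_every_post_risky(self):
        entries = [e for e in small_lexicon() if True]
        heavy = SuicideLexicon(
            entries=[type(e)(word=e.word, category=e.category, weight=3, source=e.source) for e in entries]
        )
        spec = syn.CorpusSpec(n_users_high=2, n_users_non_high=0, posts_per_user=5,
                              p_risk_word_high=1.0, p_risk_word_low=0.0)
        posts, _ = syn.make_corpus(heavy, spec, seed=1)
        m = build_matcher(heavy)
        assert all(score_post(m.find_matches(p.text)).is_risky for p in posts)

    def test_empirical_match_rate_tracks_emission_probability(self):
        """Matched-occurrence rate per token stays within 3 Monte-Carlo
        standard errors of the planted probability for each group.

        Uses the ASCII (space-separated) style so token counts are exactly
        recoverable from the text; disjoint lexicon/filler alphabets make
        hits equal planted emissions.
        """
        lx = syn.make_lexicon(category_counts={c: 3 for c in CATEGORIES},
                              vocabulary_style="ascii", seed=5)
        spec = syn.CorpusSpec(n_users_high=10, n_users_non_high=10, posts_per_user=30,
                              tokens_per_post=(30, 40), p_risk_word_high=0.08,
                              p_risk_word_low=0.02, vocabulary_style="ascii")
        posts, truth = syn.make_corpus(lx, spec, seed=5)
        m = build_matcher(lx)
        for group, p in (("high", 0.08), ("non_high", 0.02)):
            uids = {u for u in truth.user_ids if truth.group(u) == group}
            n_tokens = sum(len(post.text.split()) for post in posts if post.user_id in uids)
            n_hits = sum(len(m.find_matches(post.text)) for post in posts if post.user_id in uids)
            assert n_tokens >= 10_000
            se = np.sqrt(p * (1 - p) / n_tokens)
            assert abs(n_hits / n_tokens - p) < 3 * se

    def test_timestamps_inside_span(self):
        lx = small_lexicon()
        spec = syn.CorpusSpec(n_users_high=2, n_users_non_high=2, posts_per_user=10,
                              time_span_days=30.0)
        posts, _ = syn.make_corpus(lx, spec, seed=2)
        for p in posts:
            assert (spec.anchor - p.timestamp).total_seconds() <= 30 * 86400
            assert p.timestamp <= spec.anchor

    def test_filler_tokens_disjoint_from_lexicon(self):
        lx = small_lexicon()
        spec = syn.CorpusSpec(n_users_high=2, n_users_non_high=2, posts_per_user=10,
                              p_risk_word_high=0.0, p_risk_word_low=0.0)
        posts, _ = syn.make_corpus(lx, spec, seed=3)
        lex_chars = {ch for w in lx.words for ch in w}
        filler_chars = {ch for p in posts for ch in p.text}
        assert not (lex_chars & filler_chars)

    def test_determinism(self):
        lx = small_lexicon()
        spec = syn.CorpusSpec(n_users_high=2, n_users_non_high=2, posts_per_user=3)
        a, _ = syn.make_corpus(lx, spec, seed=9)
        b, _ = syn.make_corpus(lx, spec, seed=9)
        assert a == b


class TestMakeSps:
    def truth(self, n_high, n_low):
        rows = [{"user_id": f"h{i}", "group": "high", "emission_p": 0.08} for i in range(n_high)]
        rows += [{"user_id": f"l{i}", "group": "non_high", "emission_p": 0.02} for i in range(n_low)]
        return syn.GroundTruth(rows)

    def test_zero_sd_totals_exact(self):
        records = syn.make_sps(self.truth(3, 3), mean_high=100, mean_low=60, sd=0.0, seed=0)
        totals = {r.user_id: r.total for r in records}
        assert all(totals[f"h{i}"] == 100 for i in range(3))
        assert all(totals[f"l{i}"] == 60 for i in range(3))

    def test_pooled_mean_near_reference_at_cohort_scale(self):
        """With the ~16%-high cohort mix, default group means pool back to
        the reference mean 69.35 (within 3 standard errors at n=788)."""
        records = syn.make_sps(self.truth(125, 663), seed=11)
        totals = np.array([r.total for r in records])
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - 69.35) < 3 * se

    def test_totals_clipped_to_valid_range(self):
        records = syn.make_sps(self.truth(50, 50), mean_high=150, mean_low=20, sd=30, seed=2)
        assert all(36 <= r.total <= 144 for r in records)

    def test_determinism(self):
        t = self.truth(5, 5)
        assert syn.make_sps(t, seed=4) == syn.make_sps(t, seed=4)


class TestMakeExpertRatings:
    def scored_posts(self, seed=0, n=200):
        lx = small_lexicon()
        spec = syn.CorpusSpec(n_users_high=5, n_users_non_high=5, posts_per_user=20,
                              p_risk_word_high=0.10, p_risk_word_low=0.01)
        posts, _ = syn.make_corpus(lx, spec, seed=seed)
        m = build_matcher(lx)
        return [score_post(m.find_matches(p.text)) for p in posts[:n]]

    def test_noiseless_ratings_perfectly_correlated_with_scores(self):
        scores = self.scored_posts()
        overall, _ = syn.make_expert_ratings(scores, syn.ExpertRatingSpec(noise_sd=0.0), seed=0)
        totals = [s.total_score for s in scores]
        assert pearson(overall, totals) == pytest.approx(1.0, abs=1e-9)

    def test_huge_noise_destroys_correlation(self):
        scores = self.scored_posts(n=1000)
        overall, _ = syn.make_expert_ratings(scores, syn.ExpertRatingSpec(noise_sd=200.0), seed=1)
        totals = [s.total_score for s in scores]
        assert abs(pearson(overall, totals)) < 0.15

    def test_correlation_decreases_with_noise(self):
        """Convergent validity degrades monotonically over a noise grid."""
        scores = self.scored_posts(n=600)
        totals = [s.total_score for s in scores]
        rs = []
        for noise in (0.0, 2.0, 50.0):
            overall, _ = syn.make_expert_ratings(scores, syn.ExpertRatingSpec(noise_sd=noise), seed=2)
            rs.append(pearson(overall, totals))
        assert rs[0] > rs[1] > rs[2]

    def test_ratings_on_scale_and_mean_aggregation(self):
        scores = self.scored_posts(n=50)
        overall, by_cat = syn.make_expert_ratings(scores, syn.ExpertRatingSpec(noise_sd=1.0, aggregation="mean"), seed=3)
        assert by_cat.shape == (50, len(CATEGORIES))
        assert (by_cat >= 1.0).all() and (by_cat <= 7.0).all()
        assert overall == pytest.approx(by_cat.mean(axis=1))

    def test_determinism(self):
        scores = self.scored_posts(n=30)
        a, _ = syn.make_expert_ratings(scores, seed=5)
        b, _ = syn.make_expert_ratings(scores, seed=5)
        assert np.array_equal(a, b)


class TestMakeEmbeddings:
    def test_same_seed_identical_vectors(self):
        lx = small_lexicon(n_per_cat=1)
        m1, s1 = syn.make_embeddings(lx, synonyms_per_word=2, n_distractors=10, dim=12, seed=6)
        m2, s2 = syn.make_embeddings(lx, synonyms_per_word=2, n_distractors=10, dim=12, seed=6)
        assert m1.words == m2.words and s1 == s2
        assert np.array_equal(m1._unit, m2._unit)

    def test_planted_margin_holds(self):
        lx = small_lexicon(n_per_cat=1)
        model, synonyms = syn.make_embeddings(lx, synonyms_per_word=3, n_distractors=50, dim=16, seed=7)
        for seed_word, syns in synonyms.items():
            worst = min(model.similarity(seed_word, s) for s in syns)
            others = [w for w in model.words if w != seed_word and w not in syns]
            assert worst > max(model.similarity(seed_word, o) for o in others)

    def test_no_synonyms_no_distractors_leaves_lexicon_only(self):
        lx = small_lexicon(n_per_cat=1)
        model, synonyms = syn.make_embeddings(lx, synonyms_per_word=0, n_distractors=0, dim=8, seed=8)
        assert set(model.words) == set(lx.words)
        assert all(not v for v in synonyms.values())

    def test_dim_too_small_rejected(self):
        with pytest.raises(ValueError):
            syn.make_embeddings(small_lexicon(), dim=1)
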