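"""Similarity metrics, matcher-vs-oracle equivalence, and page scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import healthfact as hf
from healthfact.documents import Sentence


def LS(sent_id, text, label, pmid=None):
    return hf.LabeledSentence(Sentence(sent_id, text, (0, len(text))), label, pmid)


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, -1.2, 4.0])
        assert hf.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert hf.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert hf.cosine_similarity([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            hf.cosine_similarity([0, 0], [1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hf.cosine_similarity([1, 2], [1, 2, 3])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=8),
           st.lists(st.floats(-10, 10), min_size=3, max_size=8))
    def test_symmetry_and_bound(self, u, v):
        n = min(len(u), len(v))
        u, v = np.array(u[:n]), np.array(v[:n])
        if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
            return
        s = hf.cosine_similarity(u, v)
        assert s == pytest.approx(hf.cosine_similarity(v, u))
        assert -1.0 - 1e-9 <= s <= 1.0 + 1e-9


class TestJaccard:
    def test_identity(self):
        assert hf.jaccard_similarity("Pain and fever.", "Pain and fever.") == 1.0

    def test_disjoint(self):
        assert hf.jaccard_similarity("alpha beta", "gamma delta") == 0.0

    def test_hand_computed_example(self):
        assert hf.jaccard_similarity("high blood pressure", "blood pressure medication") == 0.5

    def test_both_empty_token_sets(self):
        assert hf.jaccard_similarity("...", "!!!") == 1.0

    def test_punctuation_and_case_insensitive(self):
        assert hf.jaccard_similarity("Fever, pain!", "fever pain") == 1.0

    def test_distance_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(9)
        words = ["pain", "fever", "cough", "fatigue", "rash", "chills", "ache"]
        for _ in range(200):
            a, b, c = (" ".join(rng.choice(words, size=rng.integers(1, 6)))
                       for _ in range(3))
            dab = 1 - hf.jaccard_similarity(a, b)
            dbc = 1 - hf.jaccard_similarity(b, c)
            dac = 1 - hf.jaccard_similarity(a, c)
            assert dac <= dab + dbc + 1e-12


class TestEmbedSentences:
    def test_identical_texts_identical_vectors(self, embedder):
        v = hf.embed_sentences(["blood pressure", "blood pressure"], embedder)
        assert v[0].values == v[1].values

    def test_shape_contract(self, embedder):
        v = hf.embed_sentences(["alpha", "beta"], embedder)
        assert len(v) == 2 and len(v[0].values) == len(v[1].values) == 256
        assert v[0].model_id == "feature-hashing-256"

    def test_bag_of_tokens_order_invariance(self, embedder):
        v = hf.embed_sentences(["blood pressure", "pressure blood"], embedder)
        assert v[0].values == v[1].values


def brute_force_matches(web, articles, metric, threshold, embedder):
    """Independent oracle: nested loop over all pairs, no shortcuts."""
    out = []
    for w in web:
        for a in articles:
            if w.label == "neutral" or a.label != w.label:
                continue
            if metric == "cosine":
                score = hf.cosine_similarity(embedder(w.sentence.text),
                                             embedder(a.sentence.text))
            else:
                score = hf.jaccard_similarity(w.sentence, a.sentence)
            if score >= threshold:
                out.append((w.sentence.sent_id, a.sentence.sent_id, round(score, 4)))
    return sorted(out)


class TestMatcher:
    def test_unattainable_threshold(self, embedder):
        web = [LS("w:0", "pain and fever", "semiology")]
        art = [LS("a:0", "pain and fever", "semiology", "11")]
        assert hf.match_sentences(web, art, threshold=1.01, embedder=embedder) == []

    @pytest.mark.parametrize("metric", ["cosine", "jaccard"])
    def test_oracle_equivalence_on_random_fixtures(self, metric, embedder):
        rng = np.random.default_rng(17)
        words = ["pain", "fever", "cough", "treatment", "surgery", "rate",
                 "cases", "risk", "doctor", "screening", "blood", "pressure"]
        labels = ["semiology", "epidemiology", "management", "neutral"]
        for trial in range(10):
            web = [LS(f"w:{i}", " ".join(rng.choice(words, size=rng.integers(2, 7))),
                      labels[int(rng.integers(4))]) for i in range(rng.integers(3, 8))]
            art = [LS(f"a:{j}", " ".join(rng.choice(words, size=rng.integers(2, 7))),
                      labels[int(rng.integers(4))], str(100 + j))
                   for j in range(rng.integers(3, 12))]
            got = hf.match_sentences(web, art, metric=metric, threshold=0.5,
                                     embedder=embedder)
            expect = brute_force_matches(web, art, metric, 0.5, embedder)
            assert sorted((m.web_sent_id, m.article_sent_id, m.score) for m in got) == expect

    def test_category_stratification(self, embedder):
        web = [LS("w:0", "identical words here", "semiology")]
        art = [LS("a:0", "identical words here", "management", "11")]
        assert hf.match_sentences(web, art, embedder=embedder) == []

    def test_neutral_never_matches(self, embedder):
        web = [LS("w:0", "identical words here", "neutral")]
        art = [LS("a:0", "identical words here", "neutral", "11")]
        assert hf.match_sentences(web, art, embedder=embedder) == []

    def test_threshold_monotonicity(self, embedder):
        rng = np.random.default_rng(5)
        words = ["pain", "fever", "cough", "rash", "ache"]
        web = [LS(f"w:{i}", " ".join(rng.choice(words, 3)), "semiology") for i in range(6)]
        art = [LS(f"a:{j}", " ".join(rng.choice(words, 3)), "semiology", "9") for j in range(6)]
        sizes = [len(hf.match_sentences(web, art, threshold=t, embedder=embedder))
                 for t in (0.2, 0.5, 0.8, 0.95)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_article_side(self, embedder):
        web = [LS("w:0", "pain and fever", "semiology")]
        assert hf.match_sentences(web, [], embedder=embedder) == []

    def test_cosine_requires_embedder(self):
        with pytest.raises(ValueError):
            hf.match_sentences([], [], metric="cosine")


class TestPageReport:
    def _categorized(self, n):
        return [LS(f"d:{i}", f"sentence number {i} about pain", "semiology")
                for i in range(n)]

    def _match(self, wid, score=0.9):
        return hf.SimilarityMatch(wid, "a:0", "42", "semiology", "cosine", score)

    def test_worked_fraction_seven_of_twentyseven(self):
        cat = self._categorized(27)
        matches = [self._match(f"d:{i}") for i in range(7)]
        rep = hf.summarize_page("d", cat, matches)
        assert rep.n_categorized == 27 and rep.n_credible == 7
        assert rep.credible_fraction == pytest.approx(7 / 27)
        assert rep.credible_percent == 26

    def test_no_matches_gives_zero(self):
        rep = hf.summarize_page("d", self._categorized(5), [])
        assert rep.credible_fraction == 0.0

    def test_full_coverage_gives_one(self):
        cat = self._categorized(4)
        rep = hf.summarize_page("d", cat, [self._match(f"d:{i}") for i in range(4)])
        assert rep.credible_fraction == 1.0

    def test_neutral_only_page(self):
        neutral = [LS("d:0", "cookie banner text", "neutral")]
        rep = hf.summarize_page("d", neutral, [])
        assert rep.n_categorized == 0 and rep.credible_fraction == 0.0

    def test_best_evidence_picks_top_score_with_link(self):
        cat = self._categorized(2)
        matches = [self._match("d:0", 0.90), self._match("d:0", 0.95)]
        rep = hf.summarize_page("d", cat, matches)
        ev = rep.best_evidence["d:0"]
        assert ev["score"] == 0.95
        assert ev["pubmed_url"] == "https://pubmed.ncbi.nlm.nih.gov/42/"

    def test_unknown_match_reference_rejected(self):
        with pytest.raises(ValueError):
            hf.summarize_page("d", self._categorized(1), [self._match("other:9")])
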