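"""Thematic classifier backends, evaluation metrics, and Cohen kappa."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

import healthfact as hf
from healthfact.classify import LABELS


class TestTraining:
    def test_baseline_fits_noiseless_templates_perfectly(self, small_corpus, baseline_model):
        preds = baseline_model.predict([t for t, _ in small_corpus])
        acc = np.mean([p.label == g for p, (_, g) in zip(preds, small_corpus)])
        assert acc == 1.0

    def test_missing_class_lists_absent_classes(self, small_corpus):
        partial = [(t, g) for t, g in small_corpus if g != "management"]
        with pytest.raises(ValueError, match="management"):
            hf.train_classifier(partial, hf.ClassifierConfig(backend="keyword_baseline"))

    def test_same_seed_trains_identically(self, small_corpus):
        cfg = hf.ClassifierConfig(backend="linear", seed=5)
        held_out = [t for t, _ in small_corpus[::7]]
        m1 = hf.train_classifier(small_corpus, cfg)
        m2 = hf.train_classifier(small_corpus, cfg)
        assert [l.label for l in m1.predict(held_out)] == [l.label for l in m2.predict(held_out)]

    def test_overlong_sentence_truncated_not_rejected(self, small_corpus):
        long_text = "word " * 1000 + "pain"
        corpus = list(small_corpus) + [(long_text, "semiology")]
        model = hf.train_classifier(corpus, hf.ClassifierConfig(backend="keyword_baseline"))
        assert model.predict([long_text])[0].label in LABELS

    def test_config_validation(self):
        with pytest.raises(ValueError):
            hf.ClassifierConfig(max_seq_len=4)
        with pytest.raises(ValueError):
            hf.ClassifierConfig(epochs=0)
        with pytest.raises(ValueError):
            hf.ClassifierConfig(backend="bert")


class TestPrediction:
    @pytest.mark.parametrize("text,expected", [
        ("this disease has symptoms such as pain", "semiology"),
        ("the global prevalence rate of rheumatoid arthritis was about 0.24%", "epidemiology"),
        ("drug treatment and surgical intervention can manage the disease", "management"),
    ])
    def test_category_exemplars(self, baseline_model, text, expected):
        assert hf.predict_labels(baseline_model, [text])[0].label == expected

    def test_empty_input_gives_empty_output(self, baseline_model):
        assert hf.predict_labels(baseline_model, []) == []

    def test_order_invariance(self, baseline_model, small_corpus):
        texts = [t for t, _ in small_corpus[:40]]
        fwd = [l.label for l in hf.predict_labels(baseline_model, texts)]
        rev = [l.label for l in hf.predict_labels(baseline_model, texts[::-1])]
        assert fwd == rev[::-1]

    def test_confidence_is_probability_of_chosen_label(self, baseline_model):
        lab = hf.predict_labels(baseline_model, ["symptoms include pain and fatigue"])[0]
        assert 0.0 <= lab.confidence <= 1.0


class TestEvaluation:
    def test_perfect_agreement_gives_unit_metrics(self):
        gold = ["neutral", "semiology", "epidemiology", "management"] * 3
        rep = hf.evaluate_classification(gold, gold)
        for lab in LABELS:
            assert rep.precision[lab] == rep.recall[lab] == rep.f1[lab] == 1.0
        assert rep.accuracy == 1.0

    def test_hand_computed_counts(self):
        gold = ["semiology", "semiology", "epidemiology", "management"]
        pred = ["semiology", "epidemiology", "epidemiology", "management"]
        rep = hf.evaluate_classification(gold, pred)
        assert rep.precision["semiology"] == 1.0
        assert rep.recall["semiology"] == 0.5
        assert rep.f1["semiology"] == pytest.approx(2 / 3)
        assert rep.precision["epidemiology"] == 0.5
        assert rep.recall["epidemiology"] == 1.0
        assert rep.f1["epidemiology"] == pytest.approx(2 / 3)

    def test_agrees_with_sklearn(self, small_corpus, baseline_model):
        rng = np.random.default_rng(0)
        gold = [g for _, g in small_corpus]
        pred = [rng.choice(LABELS) for _ in gold]
        rep = hf.evaluate_classification(gold, pred)
        p, r, f, s = precision_recall_fscore_support(gold, pred, labels=list(LABELS),
                                                    zero_division=0)
        for i, lab in enumerate(LABELS):
            assert rep.precision[lab] == pytest.approx(p[i])
            assert rep.recall[lab] == pytest.approx(r[i])
            assert rep.f1[lab] == pytest.approx(f[i])
            assert rep.support[lab] == s[i]

    def test_degenerate_predictor_flagged(self):
        gold = ["semiology", "epidemiology", "management"]
        pred = ["neutral"] * 3
        rep = hf.evaluate_classification(gold, pred)
        assert all(rep.f1[lab] == 0.0 for lab in LABELS)
        assert "semiology" in rep.zero_division_flags

    def test_confusion_mass_conservation_and_row_sums(self):
        rng = np.random.default_rng(1)
        gold = [str(rng.choice(LABELS)) for _ in range(97)]
        pred = [str(rng.choice(LABELS)) for _ in range(97)]
        rep = hf.evaluate_classification(gold, pred)
        assert rep.confusion.sum() == 97
        for i, lab in enumerate(LABELS):
            assert rep.confusion[i].sum() == rep.support[lab]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            hf.evaluate_classification(["neutral"], [])


class TestCohenKappa:
    def test_identical_annotations_give_one(self):
        assert hf.cohen_kappa(["x", "y", "x"], ["x", "y", "x"]) == 1.0

    def test_crossed_labeling_gives_zero(self):
        assert hf.cohen_kappa(["x", "x", "y", "y"], ["x", "y", "x", "y"]) == pytest.approx(0.0)

    def test_balanced_fully_discordant_gives_minus_one(self):
        assert hf.cohen_kappa(["x", "x", "y", "y"], ["y", "y", "x", "x"]) == pytest.approx(-1.0)

    def test_disjoint_single_category_annotators(self):
        # each annotator uses one (different) category: chance agreement is 0,
        # observed agreement is 0, so kappa is 0 under the marginal-product model
        assert hf.cohen_kappa(["x"] * 4, ["y"] * 4) == pytest.approx(0.0)

    def test_degenerate_identical_single_category(self):
        assert hf.cohen_kappa(["x"] * 5, ["x"] * 5) == 1.0

    def test_symmetry_and_sklearn_agreement(self):
        rng = np.random.default_rng(2)
        a = [str(rng.choice(LABELS)) for _ in range(60)]
        b = [str(rng.choice(LABELS)) for _ in range(60)]
        assert hf.cohen_kappa(a, b) == pytest.approx(hf.cohen_kappa(b, a))
        assert hf.cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            hf.cohen_kappa(["x"], ["x", "y"])
        with pytest.raises(ValueError):
            hf.cohen_kappa([], [])


class TestSplit:
    def test_stratified_and_deterministic(self, small_corpus):
        t1, v1 = hf.train_validation_split(small_corpus, seed=4)
        t2, v2 = hf.train_validation_split(small_corpus, seed=4)
        assert t1 == t2 and v1 == v2
        per_class = {lab: sum(1 for _, g in v1 if g == lab) for lab in LABELS}
        assert all(c == 10 for c in per_class.values())  # 20% of 50
        assert len(t1) + len(v1) == len(small_corpus)
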