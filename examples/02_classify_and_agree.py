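"""Train the thematic sentence classifier and measure agreement statistics.

Sentences fall into four classes: neutral, semiology (signs/symptoms),
epidemiology (population statistics), management (treatment/diagnosis).
The example trains the deterministic keyword baseline on a synthetic
template corpus, evaluates it on a held-out split, and shows Cohen kappa
for two simulated annotators.
"""

import healthfact as hf

corpus = hf.generate_labeled_corpus(hf.GeneratorSpec(n_per_class=100, seed=11))
train, val = hf.train_validation_split(corpus, seed=11)

model = hf.train_classifier(train, hf.ClassifierConfig(backend="keyword_baseline"))
report = hf.evaluate_classification([g for _, g in val],
                                    model.predict([t for t, _ in val]))
print("held-out accuracy:", report.accuracy, "| macro-F1:", round(report.macro_f1, 4))
for lab in hf.LABELS:
    print(f"  {lab:13s} P={report.precision[lab]:.2f} R={report.recall[lab]:.2f} "
          f"F1={report.f1[lab]:.2f} n={report.support[lab]}")

examples = [
    "this disease has symptoms such as pain and fatigue",
    "the global prevalence rate of rheumatoid arthritis was about 0.24%",
    "drug treatment and surgical intervention can control the disease",
]
print("\nexample predictions:")
for text, lab in zip(examples, hf.predict_labels(model, examples)):
    print(f"  {lab.label:13s} ({lab.confidence:.2f})  {text}")

# inter-annotator agreement: annotator B flips two labels out of a mixed
# twenty-sentence sample (five per class)
a = [val[i][1] for i in range(0, len(val), len(val) // 20)][:20]
b = list(a)
b[3], b[9] = "neutral", "management"
print("\nCohen kappa between two annotators (2/20 disagreements):",
      round(hf.cohen_kappa(a, b), 3))
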