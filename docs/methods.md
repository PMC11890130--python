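# Methods

This note documents the models and procedures behind `healthfact`, the
parameters that matter, the synthetic data the tests run on, and the design
decisions taken where the problem left room.

## Problem setting

Automated fact-checking decomposes into claim detection, evidence
retrieval, and claim verification. This package automates the first two
for consumer health pages and reduces the third to a measurable proxy:
a page sentence counts as *credible* when open-access literature retrieved
for the same thematic topic contains a sentence whose similarity to it
clears a threshold. The output is evidence with links, not a truth verdict;
a sentence without a match is "unverified here", not "false" — the
retrieved sample (20 articles per query) is a tiny slice of the literature.

## Document model

A page or article is an ordered list of sentences with identifiers
`doc_id:ordinal` and 0-based half-open character spans into the cleaned
text, so every sentence is recoverable from the document by slicing.

**Boilerplate removal** follows the stopword-density family of heuristics:
after discarding `script/style/nav/header/footer/aside/form` subtrees,
each leaf-most text block is kept only if it has ≥ 8 words, ≥ 20% function
words (a packaged 318-word English list), and ≤ 40% of its characters
inside anchors. The three thresholds are a `BoilerplateConfig`; the
defaults are a standard operating point for English prose and were not
tuned. Navigation and link lists fail the stopword-density and
link-density gates; keyword lists fail stopword density; short fragments
fail the length gate.

**Sentence segmentation** is rule-based for exact reproducibility: split
at `.!?` when followed by whitespace or end of text, guarded by a packaged
abbreviation list (`e.g.`, `Dr.`, `et al.`, …), a decimal rule (a period
between digits never splits, so "0.24%" survives), and a single-initial
rule; newlines (paragraph breaks) always close a sentence; fragments under
3 characters are dropped. A statistical segmenter would handle rare edge
cases better but would make byte-identical reruns dependent on model
versions.

## Thematic classification

Four classes: `neutral`, `semiology`, `epidemiology`, `management`, in
that fixed order (also the tie-break order). Two backends share the
training/prediction interface:

- **Keyword baseline** — scores a sentence for class *c* by summing the
  training-set relative frequencies of its tokens in class *c* and taking
  the argmax. No smoothing: the backend exists to be exactly reproducible
  and hand-checkable, and serves as the deterministic default for offline
  runs.
- **Linear backend** — L2-normalized hashed bag-of-words (FNV-1a, 4096
  buckets) into a softmax regression trained with mini-batch Adam.
  Defaults: learning rate 3×10⁻⁵, weight decay 10⁻³, 3 epochs, batch 32,
  maximum 128 tokens per sentence (longer input is truncated, never
  rejected), fixed shuffling seed. These are the best-trial values of the
  hyperparameter search adopted by the pipeline; with zero weight
  initialization the tiny learning rate still yields correct argmax
  decisions on lexically separable data because the update direction, not
  its magnitude, decides the argmax. Pretrained contextual encoders can be
  plugged in as a third backend where the environment provides them; the
  backend seam (`ClassifierConfig.backend`, `model_id`) is the integration
  point.

Both backends are order-invariant across sentences (no cross-sentence
context) and deterministic under a fixed seed.

**Evaluation** reports per-class precision/recall/F1 from a 4×4 confusion
matrix (rows gold, columns predicted); classes with no predicted positives
get precision 0 and are flagged rather than silently zeroed. **Cohen κ**
uses the textbook marginal-product chance agreement; the degenerate case
pₑ = 1 (both annotators constant and identical) is defined as κ = 1.
Train/validation splitting is 80/20, stratified per class, seeded — the
split protocol is the package's own choice.

## Term extraction and query building

MeSH extraction resolves descriptor names, their comma-inverted forms
("Arthritis, Rheumatoid" ↔ "rheumatoid arthritis"), and entry terms
against the text via a greedy longest-match scan over stem-normalized
tokens (light plural stripping only). Confidence is the mention count
normalized by the most-mentioned descriptor; the default acceptance
threshold is 0.5. Descriptors absent from the loaded vocabulary are
dropped with a warning because grouping needs tree numbers. The packaged
vocabulary is a ~55-descriptor synthetic mini-fixture shaped like the NLM
ASCII export reduction (`descriptor ⟶ tree numbers ⟶ entry terms` TSV)
covering seven disease areas; a full export loads through the same reader.

Keyphrases are 1–3-gram candidates that neither start nor end with a
stopword, never cross a sentence boundary, and contain no bare numbers.
The default ranker scores count × length normalized to (0, 1]; the
embedding ranker scores cosine similarity between the document vector and
each candidate's vector under any supplied embedder. Ties break
alphabetically; `top_n` defaults to 5 — AND-combining many phrases drives
retrieval toward zero hits, so the keyphrase subquery is kept short.
Phrases duplicating an extracted MeSH descriptor are removed
case-insensitively.

Queries are explicit trees (`Term`/`Op`), emitted with multi-word terms
double-quoted, embedded quotes stripped, MeSH leaves tagged
`[MeSH Terms]`, keyphrases untagged (all-fields). Top-level tree
categories are keyed by the leading letter of the tree number rather than
a hard-coded category count, so any vocabulary edition works; a term whose
tree numbers span several letters is replicated into each group, and a
term with no tree numbers goes to a reserved group "X". A recursive-
descent parser for the emitted grammar ships with the builder; the
round-trip property (emit ∘ parse = identity on trees) is enforced by
randomized tests, as is the operator law: *g* groups of sizes n₁…n_g give
exactly (g−1) ANDs and Σ(nᵢ−1) ORs in the MeSH subquery.

## Retrieval

Live mode uses NCBI E-utilities with relevance ("Best Match") sort and
appends `free full text[Filter]` plus the systematic-review/meta-analysis
publication-type clause; the open-access filter string is configurable
(PMC OA subset is an alternative reading of "open access"). Etiquette:
configurable email/API key and exponential backoff on failure. Fixture
mode ranks a JSONL store by the number of distinct query-term tokens an
article contains (title + text + MeSH terms), descending, ties by
ascending PMID — a pure function of (query, store). Articles with no
retrievable text are flagged excluded, as are PMIDs on a user exclusion
list (the mechanized form of a manual title-relevance review); exclusion
never re-ranks survivors.

## Similarity matching and page scoring

Sentences embed through any callable `text → vector`; the shipped default
is a 256-dimensional signed feature-hashing bag-of-tokens embedder
(FNV-1a bucket, sign from a high hash bit, integer arithmetic only, hence
bit-identical across platforms). Matching compares each web sentence only
against article sentences of the same category — neutral sentences on
either side are excluded — and keeps pairs at or above the threshold,
0.87 by default, applied to cosine on its raw [−1, 1] scale and to Jaccard
on [0, 1]. Cosine over contextual-style embeddings is the default metric;
Jaccard is retained for comparison runs. Scores are reported to 4
decimals; report percentages round half-even to integers. Degenerate
conventions: cosine of a zero vector is an error (undefined direction);
Jaccard of two empty token sets is 1.

A page report counts `n_categorized` (non-neutral web sentences),
`n_credible` (those with ≥ 1 match), their ratio (0 when nothing is
categorized), and per credible sentence the best-scoring evidence sentence
with its PubMed link.

## Synthetic data

The generator stands in for a non-public annotated page corpus and for
live PubMed; it emulates the *structure* of the task, not the texture of
real prose:

- **Labeled corpus** — per-class template sentences over seven disease
  areas (rheumatoid arthritis, COPD, COVID-19, hypertension, lung cancer,
  prostate cancer, diabetes), instantiated with seeded draws of years,
  percentages, counts and symptom lexicons. Templates are lexically
  separable by construction at zero noise, so the keyword baseline is
  exact on them — passing that test shows the plumbing is correct, not
  that real pages are this easy. Class-balanced by default
  (`n_per_class`), unlike real pages where neutral dominates.
- **Planted article store** — one web page per disease (3 sentences per
  non-neutral category + 2 neutral), and one article per
  (disease, category) whose sentences contain near-duplicates of a chosen
  fraction (`overlap_fraction`, seeded deterministic choice) of the web
  sentences, plus distractor draws rejected if their token bag collides
  with any web sentence. The emitted ground-truth key lists every planted
  pair, making recovery exactly measurable.
- **Noise** — `noise_rate` is the probability of shuffling a sentence's
  token order. This perturbs order-sensitive encoders while leaving
  bag-of-token representations (the baseline classifier, the hashing
  embedder, Jaccard) unchanged, so under the shipped backends recovery is
  only weakly anti-monotone in noise (it cannot increase).

Near-orthogonality of the hashing embedder is empirical, not exact: over
token-disjoint template sentences the mean |cosine| is below 0.1 with a
collision tail observed up to ≈ 0.21 at dimension 256 — far below the
0.87 match threshold, so collisions cannot create matches.

## Problem sizes

The test suite and the acceptance script use 200 randomized term sets for
the query grammar check, 50 random fixtures (≤ 10³ sentence pairs each)
for matcher/oracle equivalence, 400 sentences per class for classifier
checks, and the 7-page planted study for recovery and end-to-end
determinism; the whole suite runs in seconds on one CPU.

## Known limitations

- Credibility here is lexical/semantic *similarity*, not entailment: a
  high-scoring pair can disagree in meaning (a documented failure mode of
  threshold-based matching; the shipped regression check on one such
  sentence pair requires a pretrained contextual encoder backend to
  reproduce the reported high score — the lexical embedder scores it
  low). Stance detection is out of scope.
- The dictionary MeSH backend does no synonym expansion beyond entry terms
  and light stemming; recall on real pages depends on the vocabulary
  loaded.
- Retrieval quality in fixture mode is term overlap, deliberately simpler
  than PubMed's Best Match; no query relaxation is attempted when a query
  returns nothing.
- No article-quality weighting (journal, recency, retraction status):
  every retrieved sentence counts equally as evidence.
- Pages that resist text extraction simply report an extraction failure;
  there is no machine-readable criterion for "extraction restricted".
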