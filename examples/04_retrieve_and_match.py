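"""Retrieve evidence from an offline article store and match sentences.

Builds a tiny JSONL fixture store, ranks it against a query by term
overlap, fetches and segments the top articles, then matches a web
sentence against same-category article sentences at the 0.87 cosine
threshold.  (Live PubMed retrieval uses the same interface with
mode="live" and an NCBI email.)
"""

import json
import tempfile
from pathlib import Path

import healthfact as hf

store_rows = [
    {"pmid": "101", "title": "Hypertension prevalence meta-analysis",
     "text": "The global prevalence of hypertension keeps rising in adults. "
             "Risk increases with age and obesity.",
     "mesh_terms": ["Hypertension", "Prevalence"]},
    {"pmid": "102", "title": "Diabetes screening review",
     "text": "Screening detects type 2 diabetes early.", "mesh_terms": ["Diabetes Mellitus"]},
]
tmp = Path(tempfile.mkdtemp())
store = tmp / "articles.jsonl"
store.write_text("\n".join(json.dumps(r) for r in store_rows) + "\n")

cfg = hf.RetrievalConfig(mode="fixture", fixture_path=str(store), max_results=20)
records = hf.search_top_articles("Hypertension[MeSH Terms] OR prevalence", cfg)
for rec in records:
    rec = hf.fetch_article_text(rec, cfg)
    print(f"rank {rec.rank}  pmid {rec.pmid}  {len(rec.sentences)} sentences  {rec.url}")

web_sentence = hf.Sentence("page:0", "The global prevalence of hypertension is rising in adults.",
                           (0, 58))
web = [hf.LabeledSentence(web_sentence, "epidemiology")]
articles = [hf.LabeledSentence(s, "epidemiology", records[0].pmid)
            for s in records[0].sentences]

matches = hf.match_sentences(web, articles, metric="cosine", threshold=0.87,
                             embedder=hf.HashingEmbedder())
print(f"\nmatches at threshold 0.87: {len(matches)}")
for m in matches:
    print(f"  {m.web_sent_id} ~ {m.article_sent_id}  {m.metric}={m.score}")

report = hf.summarize_page("page", web, matches)
print(f"\npage credibility: {report.n_credible}/{report.n_categorized} "
      f"= {report.credible_fraction:.2f} ({report.credible_percent}%)")
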