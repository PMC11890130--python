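"""End-to-end orchestration: classify -> query -> retrieve -> match -> report.

For every web page and every non-neutral thematic category present on it,
the pipeline concatenates that category's sentences, extracts MeSH terms
and keyphrases, assembles the boolean PubMed query, retrieves and fetches
the top articles, categorizes the article sentences with the *same*
classifier, and matches web sentences against same-category article
sentences.  Per-page results aggregate into credibility reports; every
intermediate artifact is written to the output directory so a run can be
inspected or resumed stage by stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .classify import ClassifierConfig, ClassifierModel, predict_labels, train_classifier
from .documents import Document
from .query import build_final_query, build_keyphrase_subquery, build_mesh_subquery, group_terms_by_category
from .retrieval import RetrievalConfig, apply_exclusions, fetch_article_text, search_top_articles
from .similarity import (DEFAULT_THRESHOLD, LabeledSentence, PageReport, match_sentences,
                         matches_tsv, summarize_page)
from .synthetic import HashingEmbedder
from .terms import MeshVocabulary, extract_keyphrases, extract_mesh_terms

logger = logging.getLogger(__name__)

CATEGORIES = ("semiology", "epidemiology", "management")


@dataclass
class PipelineConfig:
    """Full run configuration, serialized alongside every run for provenance."""

    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    retrieval: RetrievalConfig = field(default_factory=lambda: RetrievalConfig(
        mode="fixture", fixture_path="articles.jsonl"))
    metric: str = "cosine"
    threshold: float = DEFAULT_THRESHOLD
    top_n_keyphrases: int = 5
    mesh_threshold: float = 0.5
    mesh_vocabulary_path: str | None = None
    exclusion_list: tuple[str, ...] = ()
    output_dir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "classifier": self.classifier.__dict__,
            "retrieval": self.retrieval.__dict__,
            "metric": self.metric,
            "threshold": self.threshold,
            "top_n_keyphrases": self.top_n_keyphrases,
            "mesh_threshold": self.mesh_threshold,
            "mesh_vocabulary_path": self.mesh_vocabulary_path,
            "exclusion_list": list(self.exclusion_list),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        return d


@dataclass
class RunManifest:
    """Everything needed to reconstruct a run: config, queries, stages."""

    config: dict
    queries: list[dict] = field(default_factory=list)
    stages: dict[str, str] = field(default_factory=dict)
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")


def run_pipeline(
    documents: Sequence[Document],
    config: PipelineConfig,
    model: ClassifierModel | None = None,
    training_corpus: Sequence[tuple[str, str]] | None = None,
    embedder: Callable[[str], np.ndarray] | None = None,
) -> list[PageReport]:
    """Fact-check each document and return one credibility report per page.

    A trained ``model`` or a ``training_corpus`` must be supplied.  The
    default embedder is the deterministic hashing backend; pass any other
    text-to-vector callable to swap encoders.
    """
    if model is None:
        if training_corpus is None:
            raise ValueError("either a trained model or a training corpus is required")
        model = train_classifier(training_corpus, config.classifier)
    if embedder is None:
        embedder = HashingEmbedder()
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    vocabulary = MeshVocabulary.load(config.mesh_vocabulary_path)

    reports: list[PageReport] = []
    try:
        for doc in documents:
            reports.append(_process_page(doc, model, vocabulary, config, embedder, manifest, out_dir))
        manifest.stages["all"] = "ok"
    except Exception:
        manifest.failed_stage = manifest.stages.get("current", "unknown")
        if out_dir:
            manifest.write(out_dir / "run_manifest.json")
        raise
    if out_dir:
        manifest.write(out_dir / "run_manifest.json")
        with (out_dir / "page_reports.jsonl").open("w", encoding="utf-8") as fh:
            for rep in reports:
                fh.write(json.dumps(rep.to_dict(), ensure_ascii=False, sort_keys=True) + "\n")
    return reports


def _process_page(
    doc: Document,
    model: ClassifierModel,
    vocabulary: MeshVocabulary,
    config: PipelineConfig,
    embedder,
    manifest: RunManifest,
    out_dir: Path | None,
) -> PageReport:
    manifest.stages["current"] = f"classify:{doc.doc_id}"
    labels = predict_labels(model, doc.sentences)
    web_labeled = [LabeledSentence(s, lab.label) for s, lab in zip(doc.sentences, labels)]
    categorized = [w for w in web_labeled if w.label != "neutral"]
    if not categorized:
        return summarize_page(doc.doc_id, web_labeled, [])

    all_matches = []
    for category in CATEGORIES:
        cat_sents = [w for w in categorized if w.label == category]
        if not cat_sents:
            continue
        manifest.stages["current"] = f"query:{doc.doc_id}:{category}"
        text = " ".join(w.sentence.text for w in cat_sents)
        mesh_terms = extract_mesh_terms(text, vocabulary, threshold=config.mesh_threshold)
        phrases = extract_keyphrases(
            text, top_n=config.top_n_keyphrases,
            exclude=[t.descriptor.lower() for t in mesh_terms],
        )
        subqueries = [
            build_mesh_subquery(group_terms_by_category(mesh_terms)),
            build_keyphrase_subquery(phrases),
        ]
        if all(q is None for q in subqueries):
            logger.info("page %s category %s: no extractable terms; skipped",
                        doc.doc_id, category)
            continue
        query = build_final_query(subqueries)
        manifest.queries.append({"doc_id": doc.doc_id, "category": category, "query": query})

        manifest.stages["current"] = f"retrieve:{doc.doc_id}:{category}"
        records = search_top_articles(query, config.retrieval)
        records = apply_exclusions(records, config.exclusion_list)
        records = [fetch_article_text(r, config.retrieval) for r in records]

        manifest.stages["current"] = f"match:{doc.doc_id}:{category}"
        article_sents: list[LabeledSentence] = []
        for rec in records:
            if rec.excluded:
                continue
            art_labels = predict_labels(model, rec.sentences)
            for s, lab in zip(rec.sentences, art_labels):
                if lab.label == category:
                    article_sents.append(LabeledSentence(s, lab.label, rec.pmid))
        matches = match_sentences(cat_sents, article_sents, metric=config.metric,
                                  threshold=config.threshold, embedder=embedder)
        all_matches.extend(matches)

    report = summarize_page(doc.doc_id, web_labeled, all_matches)
    if out_dir:
        (out_dir / f"matches_{doc.doc_id}.tsv").write_text(matches_tsv(all_matches),
                                                           encoding="utf-8")
    return report
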