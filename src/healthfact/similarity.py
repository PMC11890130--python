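"""Sentence vectorization, similarity metrics, matching, and page scoring.

Web-page sentences are compared against literature sentences *of the same
thematic category* under cosine similarity of sentence embeddings (default)
or Jaccard similarity of token sets.  Pairs scoring at or above the 0.87
threshold mark the web sentence as credible; a page's credibility is the
fraction of its categorized (non-neutral) sentences with at least one such
match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .documents import Sentence
from .retrieval import ArticleRecord, pubmed_url

#: The similarity threshold above which a pair counts as a match.
DEFAULT_THRESHOLD = 0.87


@dataclass(frozen=True)
class EmbeddingVector:
    """A sentence embedding tagged with the backend that produced it."""

    values: tuple[float, ...]
    model_id: str
    pooling: str = "mean"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if not np.all(np.isfinite(arr)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values)


def embed_sentences(
    sentences: Sequence[Sentence | str], backend: Callable[[str], np.ndarray]
) -> list[EmbeddingVector]:
    """One vector per sentence, order preserved.

    ``backend`` maps text to a fixed-length vector; its ``model_id`` and
    ``pooling`` attributes, when present, are recorded on the output.
    """
    model_id = getattr(backend, "model_id", getattr(backend, "__name__", "custom"))
    pooling = getattr(backend, "pooling", "mean")
    out = []
    for s in sentences:
        text = s.text if isinstance(s, Sentence) else s
        if not text.strip():
            raise ValueError("cannot embed empty text")
        vec = np.asarray(backend(text), dtype=float)
        out.append(EmbeddingVector(tuple(vec.tolist()), model_id, pooling))
    if out and len({len(v.values) for v in out}) != 1:
        raise ValueError("backend produced vectors of differing lengths")
    return out


def cosine_similarity(u, v) -> float:
    """u.v / (|u| |v|); defined only for nonzero vectors of equal length."""
    ua = u.array if isinstance(u, EmbeddingVector) else np.asarray(u, dtype=float)
    va = v.array if isinstance(v, EmbeddingVector) else np.asarray(v, dtype=float)
    if ua.shape != va.shape:
        raise ValueError(f"length mismatch: {ua.shape} vs {va.shape}")
    nu, nv = np.linalg.norm(ua), np.linalg.norm(va)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(ua, va) / (nu * nv))


_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)


def _token_set(text: str) -> frozenset[str]:
    return frozenset(_PUNCT_RE.sub(" ", text.lower()).split())


def jaccard_similarity(a: Sentence | str, b: Sentence | str) -> float:
    """Intersection-over-union of lowercased, punctuation-stripped token sets.

    Two empty token sets compare as 1.0 (identical emptiness).
    """
    ta = _token_set(a.text if isinstance(a, Sentence) else a)
    tb = _token_set(b.text if isinstance(b, Sentence) else b)
    if not ta and not tb:
        return 1.0
    return len(ta & tb) / len(ta | tb)


@dataclass(frozen=True)
class SimilarityMatch:
    web_sent_id: str
    article_sent_id: str
    pmid: str
    category: str
    metric: str
    score: float

    def __post_init__(self) -> None:
        if self.metric == "cosine" and not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise ValueError("cosine score out of [-1, 1]")
        if self.metric == "jaccard" and not 0.0 <= self.score <= 1.0:
            raise ValueError("jaccard score out of [0, 1]")


@dataclass(frozen=True)
class LabeledSentence:
    """A sentence with its thematic label (and source PMID for articles)."""

    sentence: Sentence
    label: str
    pmid: str | None = None


def match_sentences(
    web: Sequence[LabeledSentence],
    articles: Sequence[LabeledSentence],
    metric: str = "cosine",
    threshold: float = DEFAULT_THRESHOLD,
    embedder: Callable[[str], np.ndarray] | None = None,
) -> list[SimilarityMatch]:
    """All same-category (web, article) sentence pairs scoring >= threshold.

    Cosine scores are compared to the threshold on the raw [-1, 1] scale
    (87% means 0.87).  Neutral sentences are expected to be excluded
    upstream and are skipped here.  Output is sorted by (web_sent_id,
    descending score, article_sent_id).
    """
    if metric not in ("cosine", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "cosine":
        if embedder is None:
            raise ValueError("cosine matching requires an embedder backend")
        web_vecs = {w.sentence.sent_id: embedder(w.sentence.text) for w in web}
        art_vecs = {a.sentence.sent_id: embedder(a.sentence.text) for a in articles}
    matches: list[SimilarityMatch] = []
    for w in web:
        if w.label == "neutral":
            continue
        for a in articles:
            if a.label != w.label or a.label == "neutral":
                continue
            if metric == "cosine":
                score = cosine_similarity(web_vecs[w.sentence.sent_id],
                                          art_vecs[a.sentence.sent_id])
            else:
                score = jaccard_similarity(w.sentence, a.sentence)
            if score >= threshold:
                matches.append(SimilarityMatch(
                    web_sent_id=w.sentence.sent_id,
                    article_sent_id=a.sentence.sent_id,
                    pmid=a.pmid or "0",
                    category=w.label,
                    metric=metric,
                    score=round(score, 4),
                ))
    matches.sort(key=lambda m: (m.web_sent_id, -m.score, m.article_sent_id))
    return matches


def labeled_article_sentences(
    records: Sequence[ArticleRecord], labels_by_sent_id: dict[str, str]
) -> list[LabeledSentence]:
    """Flatten fetched, non-excluded article records into labeled sentences."""
    out = []
    for rec in records:
        if rec.excluded:
            continue
        for s in rec.sentences:
            label = labels_by_sent_id.get(s.sent_id)
            if label and label != "neutral":
                out.append(LabeledSentence(s, label, rec.pmid))
    return out


@dataclass
class PageReport:
    """Credibility summary for one web page.

    ``credible_fraction`` is the share of categorized (non-neutral)
    sentences with at least one same-category literature match at or above
    the threshold; ``best_evidence`` maps each credible sentence to its
    top-scoring article sentence and PubMed link.
    """

    doc_id: str
    n_categorized: int
    n_credible: int
    credible_fraction: float
    matches: list[SimilarityMatch] = field(default_factory=list)
    best_evidence: dict[str, dict] = field(default_factory=dict)

    @property
    def credible_percent(self) -> int:
        """Round-half-even integer percentage."""
        return int(round(self.credible_fraction * 100))

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "n_categorized": self.n_categorized,
            "n_credible": self.n_credible,
            "credible_fraction": round(self.credible_fraction, 4),
            "credible_percent": self.credible_percent,
            "best_evidence": self.best_evidence,
            "matches": [m.__dict__ for m in self.matches],
        }


def summarize_page(
    doc_id: str,
    categorized: Sequence[LabeledSentence],
    matches: Sequence[SimilarityMatch],
) -> PageReport:
    """Aggregate matches into the page credibility report."""
    non_neutral = [c for c in categorized if c.label != "neutral"]
    ids = {c.sentence.sent_id for c in non_neutral}
    unknown = [m for m in matches if m.web_sent_id not in ids]
    if unknown:
        raise ValueError(f"matches reference unknown sentences: {unknown[0].web_sent_id}")
    best: dict[str, SimilarityMatch] = {}
    for m in matches:
        cur = best.get(m.web_sent_id)
        if cur is None or m.score > cur.score:
            best[m.web_sent_id] = m
    n_cat = len(non_neutral)
    n_cred = len(best)
    evidence = {
        wid: {
            "article_sent_id": m.article_sent_id,
            "pmid": m.pmid,
            "pubmed_url": pubmed_url(m.pmid),
            "metric": m.metric,
            "score": m.score,
            "category": m.category,
        }
        for wid, m in sorted(best.items())
    }
    return PageReport(
        doc_id=doc_id,
        n_categorized=n_cat,
        n_credible=n_cred,
        credible_fraction=(n_cred / n_cat) if n_cat else 0.0,
        matches=list(matches),
        best_evidence=evidence,
    )


def matches_tsv(matches: Sequence[SimilarityMatch]) -> str:
    """Match table serialization: one row per retained pair."""
    lines = ["web_sent_id\tarticle_sent_id\tpmid\tcategory\tmetric\tscore"]
    for m in matches:
        lines.append(f"{m.web_sent_id}\t{m.article_sent_id}\t{m.pmid}\t{m.category}"
                     f"\t{m.metric}\t{m.score:.4f}")
    return "\n".join(lines) + "\n"
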