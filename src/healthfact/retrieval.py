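"""PubMed retrieval: top-20 open-access systematic reviews / meta-analyses.

Two modes share one interface.  *Fixture* mode ranks a local JSONL article
store by term overlap with the query — a pure function of (query, store)
used for offline runs and tests.  *Live* mode talks to NCBI E-utilities
through Bio.Entrez, appending the free-full-text and publication-type
filter clauses to the query and fetching abstracts for the top hits.
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .classify import tokenize
from .documents import Sentence, segment_sentences
from .query import parse_query, query_terms

logger = logging.getLogger(__name__)

PUBMED_URL_TEMPLATE = "https://pubmed.ncbi.nlm.nih.gov/{pmid}/"
#: Filter clauses appended to every live-mode query.
LIVE_FILTER_CLAUSE = (
    ' AND (free full text[Filter])'
    ' AND ("systematic review"[Publication Type] OR "meta-analysis"[Publication Type])'
)


@dataclass
class ArticleRecord:
    """One retrieved article; ``sentences`` fills in after the text fetch."""

    pmid: str
    title: str
    rank: int
    pmcid: str | None = None
    sentences: list[Sentence] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if not self.pmid.isdigit():
            raise ValueError(f"pmid must be a numeric string, got {self.pmid!r}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")

    @property
    def url(self) -> str:
        return pubmed_url(self.pmid)


@dataclass(frozen=True)
class RetrievalConfig:
    max_results: int = 20
    mode: str = "fixture"
    fixture_path: str | None = None
    open_access_filter: str = "free full text[Filter]"
    email: str | None = None
    api_key: str | None = None
    max_retries: int = 3

    def __post_init__(self) -> None:
        if self.max_results < 1:
            raise ValueError("max_results must be >= 1")
        if self.mode not in ("live", "fixture"):
            raise ValueError(f"unknown retrieval mode {self.mode!r}")
        if self.mode == "fixture" and not self.fixture_path:
            raise ValueError("fixture mode requires fixture_path")


def pubmed_url(pmid: str) -> str:
    """Canonical article link for a PMID."""
    if not pmid.isdigit():
        raise ValueError(f"pmid must be numeric, got {pmid!r}")
    return PUBMED_URL_TEMPLATE.format(pmid=pmid)


class FixtureStore:
    """JSONL article store: ``{pmid, pmcid, title, text, mesh_terms}`` rows."""

    def __init__(self, articles: list[dict]):
        self.articles = articles
        self.by_pmid = {a["pmid"]: a for a in articles}

    @classmethod
    def load(cls, path: str | Path) -> "FixtureStore":
        articles = []
        with Path(path).open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                    row["pmid"]
                except (json.JSONDecodeError, KeyError) as exc:
                    raise ValueError(f"{path}: malformed article at line {lineno}") from exc
                articles.append(row)
        return cls(articles)


def _query_term_tokens(query: str) -> set[str]:
    try:
        terms = query_terms(parse_query(query))
    except ValueError:
        terms = [query]
    out: set[str] = set()
    for t in terms:
        out.update(tokenize(t))
    return out


def _overlap_score(article: dict, q_tokens: set[str]) -> int:
    text = " ".join(
        [article.get("title", ""), article.get("text", ""), " ".join(article.get("mesh_terms", []))]
    )
    return len(q_tokens & set(tokenize(text)))


def search_top_articles(query: str, config: RetrievalConfig) -> list[ArticleRecord]:
    """Run the final query, returning at most ``max_results`` ranked records.

    Fixture mode scores each stored article by the number of distinct query
    term tokens it contains and ranks descending, ties broken by ascending
    PMID; zero-overlap articles are not returned.  Zero hits yield an empty
    list, not an error.
    """
    if not query.strip():
        raise ValueError("empty query")
    if config.mode == "fixture":
        store = FixtureStore.load(config.fixture_path)
        q_tokens = _query_term_tokens(query)
        scored = [(a, _overlap_score(a, q_tokens)) for a in store.articles]
        scored = [(a, s) for a, s in scored if s > 0]
        scored.sort(key=lambda pair: (-pair[1], int(pair[0]["pmid"])))
        return [
            ArticleRecord(pmid=a["pmid"], pmcid=a.get("pmcid"), title=a.get("title", ""), rank=r)
            for r, (a, _) in enumerate(scored[: config.max_results], start=1)
        ]
    return _search_live(query, config)


def _search_live(query: str, config: RetrievalConfig) -> list[ArticleRecord]:
    from Bio import Entrez

    if config.email:
        Entrez.email = config.email
    if config.api_key:
        Entrez.api_key = config.api_key
    full_query = query + LIVE_FILTER_CLAUSE
    delay = 1.0
    for attempt in range(config.max_retries):
        try:
            with Entrez.esearch(db="pubmed", term=full_query, retmax=config.max_results,
                                sort="relevance") as handle:
                result = Entrez.read(handle)
            break
        except Exception as exc:  # network / NCBI hiccup
            if attempt == config.max_retries - 1:
                raise RuntimeError(f"PubMed search failed after {config.max_retries} attempts") from exc
            logger.warning("PubMed search attempt %d failed (%s); retrying", attempt + 1, exc)
            time.sleep(delay)
            delay *= 2
    pmids = list(result.get("IdList", []))
    records = []
    for r, pmid in enumerate(pmids, start=1):
        records.append(ArticleRecord(pmid=str(pmid), title="", rank=r))
    return records


def fetch_article_text(record: ArticleRecord, config: RetrievalConfig) -> ArticleRecord:
    """Populate ``record.sentences`` from the article's text; idempotent.

    Fixture mode segments the stored ``text`` field; live mode fetches the
    abstract through efetch.  A record with no retrievable text comes back
    flagged ``excluded`` with the reason logged.
    """
    if record.sentences or record.excluded:
        return record
    if config.mode == "fixture":
        store = FixtureStore.load(config.fixture_path)
        entry = store.by_pmid.get(record.pmid)
        if entry is None or not entry.get("text", "").strip():
            logger.warning("no text for pmid %s; excluding", record.pmid)
            return replace_record(record, excluded=True, reason="no retrievable text")
        text = entry["text"]
        if not record.title:
            record.title = entry.get("title", "")
    else:
        text = _fetch_live_abstract(record.pmid, config)
        if not text.strip():
            return replace_record(record, excluded=True, reason="no retrievable text")
    record.sentences = segment_sentences(text, doc_id=f"pmid{record.pmid}")
    return record


def replace_record(record: ArticleRecord, excluded: bool, reason: str) -> ArticleRecord:
    record.excluded = excluded
    record.exclusion_reason = reason
    return record


def _fetch_live_abstract(pmid: str, config: RetrievalConfig) -> str:
    from Bio import Entrez

    if config.email:
        Entrez.email = config.email
    with Entrez.efetch(db="pubmed", id=pmid, rettype="abstract", retmode="text") as handle:
        raw = handle.read()
    if isinstance(raw, bytes):
        raw = raw.decode("utf-8", "replace")
    return re.sub(r"\n{2,}", "\n", raw).strip()


def apply_exclusions(
    records: Sequence[ArticleRecord], exclusion_list: Sequence[str]
) -> list[ArticleRecord]:
    """Flag listed PMIDs as excluded; survivor ranks are left untouched."""
    known = {r.pmid for r in records}
    for pmid in exclusion_list:
        if pmid not in known:
            logger.warning("exclusion list pmid %s not among retrieved records; ignored", pmid)
    excl = set(exclusion_list)
    out = []
    for r in records:
        if r.pmid in excl and not r.excluded:
            replace_record(r, excluded=True, reason="exclusion list")
        out.append(r)
    return out
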