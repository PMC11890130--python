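"""Document model, HTML main-text extraction, and sentence segmentation.

A web page or retrieved article is reduced to an ordered list of sentences,
each carrying a stable identifier and character offsets into the cleaned
document text.  All downstream stages (classification, query building,
similarity matching) operate on these sentence units.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from lxml import etree
from lxml import html as lxml_html

logger = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"


def _load_wordlist(name: str) -> frozenset[str]:
    path = _DATA_DIR / name
    return frozenset(
        line.strip().lower()
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    )


STOPWORDS: frozenset[str] = _load_wordlist("stopwords.txt")
#: Tokens ending in "." that never terminate a sentence.
ABBREVIATIONS: frozenset[str] = _load_wordlist("abbreviations.txt")


@dataclass(frozen=True)
class Sentence:
    """One sentence of a cleaned document.

    ``sent_id`` is ``"<doc_id>:<ordinal>"``; ``char_span`` is a 0-based
    half-open offset pair into the cleaned document text, so
    ``cleaned[start:end] == text`` always holds.
    """

    sent_id: str
    text: str
    char_span: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.char_span
        if not (0 <= start < end):
            raise ValueError(f"invalid char_span {self.char_span!r}")
        if not self.text.strip():
            raise ValueError("sentence text is empty after trimming")


@dataclass
class Document:
    """A web page or article as an ordered, id-stamped sentence list."""

    doc_id: str
    source: Literal["webpage", "article"] = "webpage"
    disease_tag: str | None = None
    title: str | None = None
    sentences: list[Sentence] = field(default_factory=list)

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.sentences)

    @classmethod
    def from_text(
        cls,
        doc_id: str,
        text: str,
        source: Literal["webpage", "article"] = "webpage",
        disease_tag: str | None = None,
        title: str | None = None,
    ) -> "Document":
        sentences = segment_sentences(text, doc_id=doc_id)
        return cls(doc_id, source, disease_tag, title, sentences)

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "source": self.source,
            "disease_tag": self.disease_tag,
            "title": self.title,
            "sentences": [
                {"sent_id": s.sent_id, "text": s.text, "char_span": list(s.char_span)}
                for s in self.sentences
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Document":
        return cls(
            doc_id=d["doc_id"],
            source=d.get("source", "webpage"),
            disease_tag=d.get("disease_tag"),
            title=d.get("title"),
            sentences=[
                Sentence(s["sent_id"], s["text"], tuple(s["char_span"]))
                for s in d.get("sentences", [])
            ],
        )


# ---------------------------------------------------------------------------
# Boilerplate removal
# ---------------------------------------------------------------------------

#: Elements whose entire subtree is discarded before paragraph scoring.
_DROP_TAGS = {
    "script", "style", "nav", "header", "footer", "aside", "form",
    "noscript", "iframe", "button", "menu", "select", "option",
}
_BLOCK_TAGS = {
    "p", "h1", "h2", "h3", "h4", "h5", "h6", "li", "td", "blockquote",
    "pre", "div", "section", "article", "main", "body",
}


@dataclass(frozen=True)
class BoilerplateConfig:
    """Thresholds of the stopword-density paragraph classifier.

    A text block is kept as main content when it has at least ``min_words``
    words, at least ``min_stopword_density`` of them are function words, and
    at most ``max_link_density`` of its characters sit inside anchors.
    Defaults follow the common justext-style operating point for English.
    """

    min_words: int = 8
    min_stopword_density: float = 0.20
    max_link_density: float = 0.40


def _block_link_chars(el: etree._Element) -> int:
    return sum(len("".join(a.itertext())) for a in el.iter("a"))


def _is_good_block(text: str, link_chars: int, cfg: BoilerplateConfig) -> bool:
    words = re.findall(r"[A-Za-z][A-Za-z'-]*", text)
    if len(words) < cfg.min_words:
        return False
    stop = sum(1 for w in words if w.lower() in STOPWORDS)
    if stop / len(words) < cfg.min_stopword_density:
        return False
    if len(text) > 0 and link_chars / len(text) > cfg.max_link_density:
        return False
    return True


def extract_main_text(html: str, config: BoilerplateConfig | None = None) -> str:
    """Strip navigation, headers, footers and low-content blocks from HTML.

    Returns the concatenated main-content paragraphs separated by newlines.
    Empty or unparseable input yields an empty string (nothing to
    fact-check), never an exception.
    """
    cfg = config or BoilerplateConfig()
    if not html or not html.strip():
        return ""
    try:
        root = lxml_html.fromstring(html)
    except (etree.ParserError, ValueError):
        return ""

    for tag in _DROP_TAGS:
        for el in root.iter(tag):
            el.drop_tree()

    kept: list[str] = []
    seen_spans: set[int] = set()
    for el in root.iter():
        if not isinstance(el.tag, str) or el.tag not in _BLOCK_TAGS:
            continue
        # score only leaf-most blocks: skip containers that hold other blocks
        if any(isinstance(c.tag, str) and c.tag in _BLOCK_TAGS for c in el.iterdescendants()):
            continue
        if id(el) in seen_spans:
            continue
        seen_spans.add(id(el))
        text = re.sub(r"\s+", " ", " ".join(el.itertext())).strip()
        if not text:
            continue
        if _is_good_block(text, _block_link_chars(el), cfg):
            kept.append(text)
    return "\n".join(kept)


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

_TERMINATORS = ".!?"
_MIN_SENT_CHARS = 3


def _is_boundary(text: str, i: int) -> bool:
    """True if the terminator at position ``i`` ends a sentence."""
    ch = text[i]
    if ch in "!?":
        return True
    # decimal numbers: 0.24 — a digit on both sides is never a boundary
    if i > 0 and i + 1 < len(text) and text[i - 1].isdigit() and text[i + 1].isdigit():
        return False
    # abbreviation: the word ending here, dot included, is on the list
    m = re.search(r"(\S+)$", text[: i + 1])
    if m and m.group(1).lower() in ABBREVIATIONS:
        return False
    # initials like "J." (single capital letter)
    if m and re.fullmatch(r"[A-Z]\.", m.group(1)):
        return False
    # require end-of-text or whitespace after the terminator
    j = i + 1
    while j < len(text) and text[j] in "\"')]":
        j += 1
    if j >= len(text):
        return True
    return text[j].isspace()


def segment_sentences(text: str, doc_id: str = "doc") -> list[Sentence]:
    """Deterministic rule-based sentence splitter.

    Splits on ``. ! ?`` guarded by an abbreviation list and a decimal-number
    rule; newlines always close a sentence (paragraph breaks from the
    boilerplate stripper).  Spans index into ``text`` and are strictly
    increasing and non-overlapping; fragments shorter than 3 characters
    after trimming are dropped.
    """
    sentences: list[Sentence] = []
    if not text:
        return sentences
    start = 0
    i = 0
    n = len(text)
    ordinal = 0

    def flush(lo: int, hi: int) -> None:
        nonlocal ordinal
        raw = text[lo:hi]
        stripped = raw.strip()
        if len(stripped) < _MIN_SENT_CHARS:
            return
        lead = len(raw) - len(raw.lstrip())
        lo2 = lo + lead
        hi2 = lo2 + len(stripped)
        sentences.append(Sentence(f"{doc_id}:{ordinal}", stripped, (lo2, hi2)))
        ordinal += 1

    while i < n:
        ch = text[i]
        if ch == "\n":
            flush(start, i)
            start = i + 1
        elif ch in _TERMINATORS and _is_boundary(text, i):
            j = i + 1
            while j < n and text[j] in "\"')]":
                j += 1
            flush(start, j)
            start = j
        i += 1
    flush(start, n)
    return sentences


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------


def save_documents(documents: Iterable[Document], path: str | Path) -> None:
    """Write documents as canonical JSONL, one document per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(json.dumps(doc.to_dict(), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def load_documents(path: str | Path, format: str = "jsonl") -> list[Document]:
    """Load a corpus from JSONL or a directory of plain-text files.

    JSONL round-trips :func:`save_documents` field-for-field.  In
    ``text_dir`` mode every ``*.txt`` file becomes one document (doc_id =
    file stem) segmented on load.  Malformed JSONL lines raise an error
    naming the line number.
    """
    path = Path(path)
    if format == "jsonl":
        docs: list[Document] = []
        seen: set[str] = set()
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    d = json.loads(line)
                    if "doc_id" not in d:
                        raise KeyError("doc_id")
                    doc = Document.from_dict(d)
                except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                    raise ValueError(f"{path}: malformed document at line {lineno}: {exc}") from exc
                if doc.doc_id in seen:
                    raise ValueError(f"{path}: duplicate doc_id {doc.doc_id!r} at line {lineno}")
                seen.add(doc.doc_id)
                docs.append(doc)
        return docs
    if format == "text_dir":
        if not path.is_dir():
            raise ValueError(f"{path} is not a directory")
        docs = []
        for f in sorted(path.glob("*.txt")):
            docs.append(Document.from_text(f.stem, f.read_text(encoding="utf-8")))
        return docs
    raise ValueError(f"unknown corpus format {format!r}")
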