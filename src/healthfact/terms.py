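"""MeSH term and keyphrase extraction from one thematic category's text.

The query builder consumes two ingredient lists extracted from the
concatenated sentences of a single thematic category of a single page:

* **MeSH terms** — controlled-vocabulary descriptors with their tree
  numbers, found by a dictionary backend that exact/stemmed-matches
  descriptor names (and their entry terms) in the text.  A model-based
  multilabel tagger can be plugged in through the same interface.
* **Keyphrases** — free-text 1-4-gram phrases ranked either by term
  frequency (deterministic) or by embedding similarity between the
  document vector and candidate n-gram vectors (the KeyBERT-style scheme,
  generic over any sentence embedder).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .classify import tokenize

logger = logging.getLogger(__name__)

_TREE_NUMBER_RE = re.compile(r"^[A-Z](\d{2})(\.\d{3})*$")
_DEFAULT_VOCAB = Path(__file__).parent / "data" / "mesh_vocabulary.tsv"


@dataclass(frozen=True)
class MeshTerm:
    """A MeSH descriptor hit: canonical name, tree numbers, confidence."""

    descriptor: str
    tree_numbers: tuple[str, ...]
    score: float = 1.0

    def __post_init__(self) -> None:
        if not self.descriptor:
            raise ValueError("descriptor must be non-empty")
        for tn in self.tree_numbers:
            if not _TREE_NUMBER_RE.match(tn):
                raise ValueError(f"malformed tree number {tn!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass(frozen=True)
class KeyPhrase:
    """A free-text phrase of 1-4 lowercased tokens with a backend score."""

    phrase: str
    score: float

    def __post_init__(self) -> None:
        n = len(self.phrase.split())
        if not 1 <= n <= 4:
            raise ValueError(f"phrase must be 1-4 tokens, got {n}")
        if self.phrase != self.phrase.lower():
            raise ValueError("phrase must be lowercased")


def _stem(token: str) -> str:
    """Light suffix stripper used for dictionary matching (plural forms)."""
    if len(token) > 4 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 3 and token.endswith("es") and not token.endswith("ses"):
        return token[:-2]
    if len(token) > 3 and token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return token


def _normalize_phrase(phrase: str) -> tuple[str, ...]:
    return tuple(_stem(t) for t in tokenize(phrase))


def _uninvert(descriptor: str) -> str:
    """'Arthritis, Rheumatoid' -> 'Rheumatoid Arthritis' (NLM inverted form)."""
    parts = [p.strip() for p in descriptor.split(",")]
    if len(parts) == 2 and all(parts):
        return f"{parts[1]} {parts[0]}"
    return descriptor


class MeshVocabulary:
    """Descriptor name -> tree numbers mapping loaded from a TSV export.

    Rows are ``descriptor<TAB>tree1;tree2[<TAB>entry|terms]``.  Matching
    keys include the descriptor, its un-inverted comma form, and every
    entry term, all stem-normalized.
    """

    def __init__(self, entries: dict[str, tuple[str, ...]], match_keys: dict[tuple[str, ...], str]):
        self.entries = entries
        self._match_keys = match_keys
        self._max_key_len = max((len(k) for k in match_keys), default=0)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "MeshVocabulary":
        path = Path(path) if path else _DEFAULT_VOCAB
        entries: dict[str, tuple[str, ...]] = {}
        match_keys: dict[tuple[str, ...], str] = {}
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed vocabulary row at line {lineno}")
            descriptor = parts[0].strip()
            trees = tuple(t.strip() for t in parts[1].split(";") if t.strip())
            entries[descriptor] = trees
            surface_forms = [descriptor, _uninvert(descriptor)]
            if len(parts) > 2:
                surface_forms += [e.strip() for e in parts[2].split("|") if e.strip()]
            for form in surface_forms:
                key = _normalize_phrase(form)
                if key:
                    match_keys.setdefault(key, descriptor)
        return cls(entries, match_keys)

    def __contains__(self, descriptor: str) -> bool:
        return descriptor in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def tree_numbers(self, descriptor: str) -> tuple[str, ...]:
        return self.entries[descriptor]

    def scan(self, text: str) -> list[tuple[str, int]]:
        """Greedy longest-match scan; returns (descriptor, hit count) pairs."""
        tokens = [_stem(t) for t in tokenize(text)]
        hits: dict[str, int] = {}
        i = 0
        while i < len(tokens):
            matched = 0
            for L in range(min(self._max_key_len, len(tokens) - i), 0, -1):
                key = tuple(tokens[i : i + L])
                if key in self._match_keys:
                    d = self._match_keys[key]
                    hits[d] = hits.get(d, 0) + 1
                    matched = L
                    break
            i += matched if matched else 1
        return sorted(hits.items())


def extract_mesh_terms(
    text: str,
    vocabulary: MeshVocabulary,
    threshold: float = 0.5,
    tagger: Callable[[str], Sequence[tuple[str, float]]] | None = None,
) -> list[MeshTerm]:
    """Extract MeSH descriptors whose confidence meets ``threshold``.

    Default backend is the deterministic dictionary scanner; ``tagger``
    plugs in a model backend returning ``(descriptor, score)`` pairs.
    Descriptors missing from the vocabulary are dropped with a warning
    because the query builder needs their tree numbers.
    """
    if not text or not text.strip():
        raise ValueError("cannot extract MeSH terms from empty text")
    if vocabulary is None or len(vocabulary) == 0:
        raise ValueError("MeSH vocabulary not loaded")
    if tagger is not None:
        scored = list(tagger(text))
    else:
        hits = vocabulary.scan(text)
        max_hits = max((c for _, c in hits), default=1)
        # dictionary confidence: repeated mentions score higher, cap at 1
        scored = [(d, c / max_hits) for d, c in hits]
    out: list[MeshTerm] = []
    seen: set[str] = set()
    for descriptor, score in scored:
        if score < threshold or descriptor in seen:
            continue
        if descriptor not in vocabulary:
            logger.warning("MeSH descriptor %r not in vocabulary; dropped", descriptor)
            continue
        seen.add(descriptor)
        out.append(MeshTerm(descriptor, vocabulary.tree_numbers(descriptor), min(score, 1.0)))
    out.sort(key=lambda t: (-t.score, t.descriptor))
    return out


# ---------------------------------------------------------------------------
# Keyphrases
# ---------------------------------------------------------------------------

from .documents import STOPWORDS  # noqa: E402  (shared function-word list)


def _candidate_ngrams(text: str, max_n: int = 3) -> dict[str, int]:
    """1..max_n-grams that neither start nor end with a stopword.

    N-grams never cross a sentence/clause boundary (``.!?;:``).
    """
    counts: dict[str, int] = {}
    for segment in re.split(r"[.!?;:]", text):
        tokens = tokenize(segment)
        for n in range(1, max_n + 1):
            for i in range(len(tokens) - n + 1):
                gram = tokens[i : i + n]
                if gram[0] in STOPWORDS or gram[-1] in STOPWORDS:
                    continue
                if any(t.isdigit() for t in gram):
                    continue
                phrase = " ".join(gram)
                counts[phrase] = counts.get(phrase, 0) + 1
    return counts


def extract_keyphrases(
    text: str,
    top_n: int = 5,
    embedder: Callable[[str], np.ndarray] | None = None,
    exclude: Sequence[str] = (),
) -> list[KeyPhrase]:
    """Top ``top_n`` keyphrases, scored descending with alphabetical ties.

    Term-frequency backend by default: a candidate n-gram's score is its
    occurrence count weighted by its length in tokens, normalized to (0, 1].
    With ``embedder`` the score is instead the cosine similarity between the
    whole-document vector and the candidate's vector (the embedding-ranker
    scheme).  ``exclude`` removes phrases case-insensitively, e.g. ones
    already captured as MeSH terms.
    """
    if not text or not text.strip():
        raise ValueError("cannot extract keyphrases from empty text")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts = _candidate_ngrams(text)
    excluded = {e.lower() for e in exclude}
    if excluded:
        dropped = [p for p in counts if p in excluded]
        if dropped:
            logger.info("keyphrases deduplicated against %d excluded phrases", len(dropped))
        counts = {p: c for p, c in counts.items() if p not in excluded}
    if not counts:
        return []
    if embedder is not None:
        doc_vec = embedder(text)
        dn = np.linalg.norm(doc_vec)
        scores = {}
        for p in counts:
            v = embedder(p)
            vn = np.linalg.norm(v)
            scores[p] = float(doc_vec @ v / (dn * vn)) if dn > 0 and vn > 0 else 0.0
        # map cosine [-1,1] into [0,1] to satisfy the score contract
        scores = {p: (s + 1.0) / 2.0 for p, s in scores.items()}
    else:
        best = max(c * len(p.split()) for p, c in counts.items())
        scores = {p: c * len(p.split()) / best for p, c in counts.items()}
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [KeyPhrase(p, round(s, 6)) for p, s in ranked[:top_n]]
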