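"""Synthetic corpora, article stores, and a deterministic test embedder.

The annotated page corpus behind the pipeline is not public, so this
module generates template-based stand-ins that reproduce its structure:
four thematic sentence classes over seven disease areas, companion
web-page documents, and a mock article store with a known fraction of
planted near-duplicate sentences.  Templates are built so the classes are
lexically separable at zero noise; the noise parameter shuffles token
order within a sentence, which perturbs order-sensitive encoders while
leaving bag-of-token representations unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import _stable_hash, tokenize
from .documents import Document, Sentence

#: The seven disease areas the pipeline was exercised on.
DEFAULT_DISEASES: tuple[str, ...] = (
    "rheumatoid arthritis",
    "chronic obstructive pulmonary disease",
    "COVID-19",
    "hypertension",
    "lung cancer",
    "prostate cancer",
    "diabetes",
)

_SYMPTOMS = ("pain", "discomfort", "weakness", "fatigue", "fever", "cough",
             "stiffness", "swelling", "dizziness", "breathlessness")

_EPI_TEMPLATES = (
    "As of {year}, the global prevalence rate of {disease} was about {pct} percent.",
    "In {year}, approximately {count} new cases of {disease} were reported worldwide.",
    "The incidence of {disease} rose among adults older than {age} years.",
    "Several risk factors raise the likelihood of {disease} in the general population.",
    "Mortality attributable to {disease} reached {pct} percent in {year}.",
)
_SEM_TEMPLATES = (
    "{disease} has symptoms such as {s1}, {s2}, and {s3}.",
    "{s1} is another sign of {disease}.",
    "People living with {disease} often experience {s1} and {s2}.",
    "Early signs of {disease} include {s1} and {s2}.",
)
_MAN_TEMPLATES = (
    "Drug treatment and surgical intervention are options for managing {disease}.",
    "A complete medical examination carried out by a doctor can determine whether a person has {disease}.",
    "Doctors may prescribe medication to control {disease}.",
    "Regular screening supports the diagnosis and therapy of {disease}.",
)
_NEU_TEMPLATES = (
    "This website uses cookies to improve your browsing experience.",
    "Our newsletter brings weekly updates straight to your inbox.",
    "The reception desk of the clinic stays open from Monday to Friday.",
    "Please contact the webmaster if a link appears broken.",
    "The editorial team last reviewed this article during spring.",
)

_TEMPLATES = {
    "neutral": _NEU_TEMPLATES,
    "semiology": _SEM_TEMPLATES,
    "epidemiology": _EPI_TEMPLATES,
    "management": _MAN_TEMPLATES,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions of a synthetic run; identical specs give identical output."""

    n_per_class: int = 100
    diseases: tuple[str, ...] = DEFAULT_DISEASES
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")


def _instantiate(template: str, disease: str, rng: np.random.Generator) -> str:
    sym = rng.choice(len(_SYMPTOMS), size=3, replace=False)
    return template.format(
        disease=disease,
        year=int(rng.integers(1990, 2025)),
        pct=round(float(rng.uniform(0.05, 35.0)), 2),
        count=int(rng.integers(1, 900)) * 1000,
        age=int(rng.integers(30, 80)),
        s1=_SYMPTOMS[sym[0]], s2=_SYMPTOMS[sym[1]], s3=_SYMPTOMS[sym[2]],
    )


def _maybe_shuffle(text: str, noise_rate: float, rng: np.random.Generator) -> str:
    if noise_rate > 0 and rng.random() < noise_rate:
        tokens = text.rstrip(".").split()
        rng.shuffle(tokens)
        return " ".join(tokens) + "."
    return text


def generate_labeled_corpus(spec: GeneratorSpec) -> list[tuple[str, str]]:
    """``n_per_class`` template sentences per label as (text, label) pairs."""
    rng = np.random.default_rng(spec.seed)
    corpus: list[tuple[str, str]] = []
    for label in ("neutral", "semiology", "epidemiology", "management"):
        templates = _TEMPLATES[label]
        for i in range(spec.n_per_class):
            template = templates[i % len(templates)]
            disease = spec.diseases[int(rng.integers(len(spec.diseases)))]
            text = _instantiate(template, disease, rng)
            corpus.append((_maybe_shuffle(text, spec.noise_rate, rng), label))
    return corpus


def save_labeled_corpus(corpus: list[tuple[str, str]], path: str | Path) -> None:
    """JSONL form consumed by the classifier CLI: sent_id, text, label."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, (text, label) in enumerate(corpus):
            fh.write(json.dumps({"sent_id": f"corpus:{i}", "text": text, "label": label},
                                ensure_ascii=False))
            fh.write("\n")


def load_labeled_corpus(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
                out.append((row["text"], row["label"]))
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}: malformed labeled sentence at line {lineno}") from exc
    return out


# ---------------------------------------------------------------------------
# Companion web pages + article store with planted matches
# ---------------------------------------------------------------------------


@dataclass
class PlantedPair:
    web_sent_id: str
    pmid: str
    article_sent_id: str
    category: str


@dataclass
class SyntheticStudy:
    """A web-page set, its gold labels, an article store, and the planted key."""

    documents: list[Document]
    gold_labels: dict[str, str]          # sent_id -> label (web side)
    store_rows: list[dict]               # JSONL article rows
    article_labels: dict[str, str]       # sent_id -> label (article side)
    planted: list[PlantedPair] = field(default_factory=list)

    def write_store(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for row in self.store_rows:
                fh.write(json.dumps(row, ensure_ascii=False, sort_keys=True))
                fh.write("\n")


def generate_article_store(
    spec: GeneratorSpec,
    overlap_fraction: float,
    sentences_per_category: int = 3,
    distractors_per_article: int = 4,
) -> SyntheticStudy:
    """Build one web page per disease plus a mock article store.

    A deterministic ``overlap_fraction`` of the pages' non-neutral
    sentences is planted into same-category article sentences as
    near-duplicates (token-shuffled at ``spec.noise_rate``); the remaining
    article sentences are fresh template draws guaranteed not to collide
    with any web sentence's token bag.  One article (one PMID) is emitted
    per (disease, category).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    documents: list[Document] = []
    gold: dict[str, str] = {}
    web_bags: set[frozenset[str]] = set()
    web_nonneutral: list[tuple[str, str, str, str]] = []  # (sent_id, text, label, disease)

    for disease in spec.diseases:
        doc_id = "web-" + disease.lower().replace(" ", "-")
        parts: list[tuple[str, str]] = []
        for label in ("epidemiology", "semiology", "management"):
            templates = _TEMPLATES[label]
            for i in range(sentences_per_category):
                text = _instantiate(templates[i % len(templates)], disease, rng)
                parts.append((text, label))
        for i in range(2):
            parts.append((_NEU_TEMPLATES[int(rng.integers(len(_NEU_TEMPLATES)))], "neutral"))
        sentences, pos = [], 0
        for ordinal, (text, label) in enumerate(parts):
            sent = Sentence(f"{doc_id}:{ordinal}", text, (pos, pos + len(text)))
            pos += len(text) + 1
            sentences.append(sent)
            gold[sent.sent_id] = label
            if label != "neutral":
                web_nonneutral.append((sent.sent_id, text, label, disease))
                web_bags.add(frozenset(tokenize(text)))
        documents.append(Document(doc_id, "webpage", disease, f"About {disease}", sentences))

    # deterministic planting: seeded shuffle, then the first k sentences
    order = rng.permutation(len(web_nonneutral))
    k = int(round(overlap_fraction * len(web_nonneutral)))
    planted_idx = set(order[:k].tolist())

    store_rows: list[dict] = []
    article_labels: dict[str, str] = {}
    planted: list[PlantedPair] = []
    pmid_counter = 1000001
    by_bucket: dict[tuple[str, str], list[tuple[str, str | None]]] = {}
    for j, (sent_id, text, label, disease) in enumerate(web_nonneutral):
        if j in planted_idx:
            dup = _maybe_shuffle(text, spec.noise_rate, rng)
            by_bucket.setdefault((disease, label), []).append((dup, sent_id))

    for disease in spec.diseases:
        for label in ("epidemiology", "semiology", "management"):
            bucket = by_bucket.get((disease, label), [])
            texts: list[tuple[str, str | None]] = list(bucket)
            templates = _TEMPLATES[label]
            added = 0
            while added < distractors_per_article:
                cand = _instantiate(templates[int(rng.integers(len(templates)))], disease, rng)
                if frozenset(tokenize(cand)) in web_bags:
                    continue
                texts.append((cand, None))
                added += 1
            pmid = str(pmid_counter)
            pmid_counter += 1
            doc_sid = f"pmid{pmid}"
            body_sentences = []
            for ordinal, (text, src) in enumerate(texts):
                asid = f"{doc_sid}:{ordinal}"
                article_labels[asid] = label
                body_sentences.append(text)
                if src is not None:
                    planted.append(PlantedPair(src, pmid, asid, label))
            store_rows.append({
                "pmid": pmid,
                "pmcid": f"PMC{pmid}",
                "title": f"Systematic review of {disease} {label}",
                "text": " ".join(body_sentences),
                "mesh_terms": [disease, label],
            })
    return SyntheticStudy(documents, gold, store_rows, article_labels, planted)


# ---------------------------------------------------------------------------
# Deterministic embedder
# ---------------------------------------------------------------------------


class HashingEmbedder:
    """Signed feature-hashing bag-of-tokens sentence embedder.

    Each lowercased token is hashed (FNV-1a, platform-independent) to one
    of ``dim`` buckets with a +/-1 sign from a second hash bit, so the
    embedding is a pure integer-arithmetic function of the token bag:
    permutation-invariant, deterministic across runs and platforms, and
    with near-orthogonal vectors for token-disjoint sentences.
    """

    def __init__(self, dim: int = 256):
        self.dim = dim
        self.model_id = f"feature-hashing-{dim}"
        self.pooling = "mean"

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for tok in tokenize(text):
            h = _stable_hash(tok)
            sign = 1.0 if (h >> 31) & 1 == 0 else -1.0
            vec[h % self.dim] += sign
        return vec


def hashing_embedder(sentence: Sentence | str, dim: int = 256) -> np.ndarray:
    """Functional form of :class:`HashingEmbedder` for one sentence."""
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    return HashingEmbedder(dim)(text)
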