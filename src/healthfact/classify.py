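"""Thematic sentence classification and agreement statistics.

Every sentence of a page is assigned one of four thematic labels:

* ``neutral`` — no verifiable health content,
* ``semiology`` — signs and symptoms,
* ``epidemiology`` — prevalence, incidence, risk and other population statistics,
* ``management`` — treatment, prevention and diagnostic work-up.

Two trainable backends share one interface.  The ``keyword_baseline``
backend scores a sentence against per-class token frequency profiles and is
fully deterministic; the ``linear`` backend is a hashed bag-of-words
softmax regression trained by mini-batch Adam with the default
hyperparameters (learning rate 3e-5, weight decay 1e-3, 3 epochs, batch
size 32, maximum sequence length 128 tokens).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Fixed label order; also the tie-break order for equal scores.
LABELS: tuple[str, ...] = ("neutral", "semiology", "epidemiology", "management")
_LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}

_TOKEN_RE = re.compile(r"[a-z0-9][a-z0-9'-]*")


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens; punctuation dropped, decimals kept intact."""
    return _TOKEN_RE.findall(text.lower().replace("%", " percent "))


@dataclass(frozen=True)
class ThematicLabel:
    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in _LABEL_INDEX:
            raise ValueError(f"unknown label {self.label!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class ClassifierConfig:
    """Training configuration shared by both backends.

    Defaults are the best-trial values of the hyperparameter search the
    pipeline adopts: ``max_seq_len`` 128 tokens (longer sentences are
    silently truncated), learning rate 3e-5, weight decay 1e-3, 3 epochs,
    batch size 32.
    """

    backend: str = "linear"
    model_id: str = "hashed-bow-softmax"
    max_seq_len: int = 128
    learning_rate: float = 3e-5
    weight_decay: float = 1e-3
    epochs: int = 3
    batch_size: int = 32
    seed: int = 0
    n_features: int = 2**12

    def __post_init__(self) -> None:
        if self.max_seq_len < 8:
            raise ValueError("max_seq_len must be >= 8")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.backend not in ("linear", "keyword_baseline"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class ClassifierModel:
    """A trained classifier; ``predict`` is deterministic for a fixed seed."""

    config: ClassifierConfig
    # keyword baseline: per-class token relative frequencies
    class_token_freq: dict[str, dict[str, float]] | None = None
    # linear backend: weights (n_features x 4) and bias (4,)
    weights: np.ndarray | None = None
    bias: np.ndarray | None = None

    def predict(self, texts: Sequence[str]) -> list[ThematicLabel]:
        if self.config.backend == "keyword_baseline":
            return [self._predict_baseline(t) for t in texts]
        return self._predict_linear(texts)

    # -- keyword baseline ---------------------------------------------------

    def _predict_baseline(self, text: str) -> ThematicLabel:
        assert self.class_token_freq is not None
        tokens = tokenize(text)[: self.config.max_seq_len]
        scores = np.zeros(len(LABELS))
        for i, lab in enumerate(LABELS):
            freq = self.class_token_freq[lab]
            scores[i] = sum(freq.get(t, 0.0) for t in tokens)
        best = int(np.argmax(scores))  # argmax returns the first (tie-break order)
        total = scores.sum()
        conf = float(scores[best] / total) if total > 0 else 1.0 / len(LABELS)
        return ThematicLabel(LABELS[best], conf)

    # -- linear backend -----------------------------------------------------

    def _features(self, texts: Sequence[str]) -> np.ndarray:
        X = np.zeros((len(texts), self.config.n_features))
        mask = self.config.n_features - 1
        for r, text in enumerate(texts):
            for tok in tokenize(text)[: self.config.max_seq_len]:
                X[r, _stable_hash(tok) & mask] += 1.0
        norms = np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
        return X / norms

    def _predict_linear(self, texts: Sequence[str]) -> list[ThematicLabel]:
        assert self.weights is not None and self.bias is not None
        if not texts:
            return []
        logits = self._features(texts) @ self.weights + self.bias
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        out = []
        for row in probs:
            best = int(np.argmax(row))
            out.append(ThematicLabel(LABELS[best], float(row[best])))
        return out


def _stable_hash(token: str) -> int:
    """FNV-1a over UTF-8 bytes — platform-independent, unlike ``hash``."""
    h = 0x811C9DC5
    for b in token.encode("utf-8"):
        h = ((h ^ b) * 0x01000193) & 0xFFFFFFFF
    return h


def train_classifier(
    corpus: Sequence[tuple[str, str]], config: ClassifierConfig | None = None
) -> ClassifierModel:
    """Train a thematic classifier from ``(text, label)`` pairs.

    Every class must be represented at least once; texts longer than
    ``max_seq_len`` tokens are truncated, never rejected.
    """
    config = config or ClassifierConfig()
    present = {lab for _, lab in corpus}
    missing = [lab for lab in LABELS if lab not in present]
    if missing:
        raise ValueError(f"training corpus lacks examples of: {', '.join(missing)}")
    for text, lab in corpus:
        if lab not in _LABEL_INDEX:
            raise ValueError(f"unknown label {lab!r}")
        if not text.strip():
            raise ValueError("training corpus contains an empty text")

    if config.backend == "keyword_baseline":
        return _train_baseline(corpus, config)
    return _train_linear(corpus, config)


def _train_baseline(corpus, config: ClassifierConfig) -> ClassifierModel:
    freq: dict[str, dict[str, float]] = {lab: {} for lab in LABELS}
    totals = {lab: 0 for lab in LABELS}
    for text, lab in corpus:
        toks = tokenize(text)[: config.max_seq_len]
        for t in toks:
            freq[lab][t] = freq[lab].get(t, 0.0) + 1.0
        totals[lab] += len(toks)
    for lab in LABELS:
        tot = max(totals[lab], 1)
        freq[lab] = {t: c / tot for t, c in freq[lab].items()}
    return ClassifierModel(config=config, class_token_freq=freq)


def _train_linear(corpus, config: ClassifierConfig) -> ClassifierModel:
    model = ClassifierModel(
        config=config,
        weights=np.zeros((config.n_features, len(LABELS))),
        bias=np.zeros(len(LABELS)),
    )
    X = model._features([t for t, _ in corpus])
    y = np.array([_LABEL_INDEX[lab] for _, lab in corpus])
    rng = np.random.default_rng(config.seed)
    W, b = model.weights, model.bias
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(corpus)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            Xb, yb = X[idx], y[idx]
            logits = Xb @ W + b
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(len(idx)), yb] -= 1.0
            p /= len(idx)
            gW = Xb.T @ p + config.weight_decay * W
            gb = p.sum(axis=0)
            step += 1
            for g, m, v, param in ((gW, mW, vW, W), (gb, mb, vb, b)):
                m *= beta1; m += (1 - beta1) * g
                v *= beta2; v += (1 - beta2) * g * g
                mhat = m / (1 - beta1**step)
                vhat = v / (1 - beta2**step)
                param -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
    return model


def predict_labels(model: ClassifierModel, sentences: Sequence) -> list[ThematicLabel]:
    """Label sentences (objects with ``.text`` or plain strings), order preserved."""
    texts = [s.text if hasattr(s, "text") else s for s in sentences]
    return model.predict(texts)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-class precision/recall/F1 with the underlying confusion matrix.

    ``confusion`` rows are gold labels, columns predictions, both in the
    fixed label order.  Classes with no predicted positives receive
    precision 0 by convention and are listed in ``zero_division_flags``.
    """

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    confusion: np.ndarray
    zero_division_flags: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        total = self.confusion.sum()
        return float(np.trace(self.confusion) / total) if total else 0.0

    @property
    def macro_f1(self) -> float:
        return float(np.mean([self.f1[lab] for lab in LABELS]))

    def to_dict(self) -> dict:
        return {
            "labels": list(LABELS),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
            "confusion_matrix": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "zero_division_flags": self.zero_division_flags,
        }

    def confusion_tsv(self) -> str:
        lines = ["gold\\pred\t" + "\t".join(LABELS)]
        for i, lab in enumerate(LABELS):
            lines.append(lab + "\t" + "\t".join(str(int(c)) for c in self.confusion[i]))
        return "\n".join(lines) + "\n"


def _as_label_str(x) -> str:
    return x.label if isinstance(x, ThematicLabel) else x


def evaluate_classification(gold: Sequence, predicted: Sequence) -> EvalReport:
    """Confusion matrix and per-class precision/recall/F1."""
    if len(gold) != len(predicted):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(predicted)} predicted")
    cm = np.zeros((len(LABELS), len(LABELS)), dtype=np.int64)
    for g, p in zip(gold, predicted):
        cm[_LABEL_INDEX[_as_label_str(g)], _LABEL_INDEX[_as_label_str(p)]] += 1
    precision, recall, f1, support = {}, {}, {}, {}
    flags = []
    for i, lab in enumerate(LABELS):
        tp = cm[i, i]
        pred_pos = cm[:, i].sum()
        gold_pos = cm[i, :].sum()
        if pred_pos == 0:
            flags.append(lab)
        precision[lab] = float(tp / pred_pos) if pred_pos else 0.0
        recall[lab] = float(tp / gold_pos) if gold_pos else 0.0
        denom = precision[lab] + recall[lab]
        f1[lab] = 2 * precision[lab] * recall[lab] / denom if denom else 0.0
        support[lab] = int(gold_pos)
    return EvalReport(precision, recall, f1, support, cm, flags)


def cohen_kappa(annotations_a: Sequence, annotations_b: Sequence) -> float:
    """Chance-corrected agreement between two annotators.

    kappa = (p_o - p_e) / (1 - p_e), with the expected agreement p_e taken
    from the product of the two annotators' marginal label frequencies.
    When p_e = 1 (both annotators use a single identical category) the
    statistic is defined as 1 for identical annotations.
    """
    a = [_as_label_str(x) for x in annotations_a]
    b = [_as_label_str(x) for x in annotations_b]
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty annotation lists")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    cats = sorted(set(a) | set(b))
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def train_validation_split(
    corpus: Sequence[tuple[str, str]], validation_fraction: float = 0.2, seed: int = 0
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """80/20 split stratified by class, deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[tuple[str, str]]] = {}
    for item in corpus:
        by_class.setdefault(item[1], []).append(item)
    train: list[tuple[str, str]] = []
    val: list[tuple[str, str]] = []
    for lab in sorted(by_class):
        items = by_class[lab]
        order = rng.permutation(len(items))
        n_val = max(1, int(round(len(items) * validation_fraction)))
        for j, k in enumerate(order):
            (val if j < n_val else train).append(items[k])
    return train, val
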