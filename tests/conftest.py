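import pytest

import healthfact as hf


@pytest.fixture(scope="session")
def vocabulary() -> hf.MeshVocabulary:
    return hf.MeshVocabulary.load()


@pytest.fixture(scope="session")
def small_corpus() -> list[tuple[str, str]]:
    """Noiseless 50-per-class template corpus, fixed seed."""
    return hf.generate_labeled_corpus(hf.GeneratorSpec(n_per_class=50, seed=11))


@pytest.fixture(scope="session")
def baseline_model(small_corpus) -> hf.ClassifierModel:
    return hf.train_classifier(small_corpus, hf.ClassifierConfig(backend="keyword_baseline"))


@pytest.fixture(scope="session")
def embedder() -> hf.HashingEmbedder:
    return hf.HashingEmbedder()


@pytest.fixture()
def study(tmp_path):
    """Planted synthetic study (overlap 0.5) with its store written to disk."""
    s = hf.generate_article_store(hf.GeneratorSpec(seed=3), overlap_fraction=0.5)
    path = tmp_path / "articles.jsonl"
    s.write_store(path)
    return s, path
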