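import pytest

from pmir.synthetic import GeneratorConfig, generate_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """The default reference benchmark (5,000 docs, 10 topics, seed 7)."""
    return generate_benchmark(GeneratorConfig())


@pytest.fixture(scope="session")
def small_benchmark():
    """A scaled-down benchmark for fast orchestration tests."""
    return generate_benchmark(
        GeneratorConfig(n_docs=400, n_topics=3, n_bearing_per_topic=25, vocab_size=500, seed=11)
    )
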