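import numpy as np
import pytest

from rfslda import CountTable, LabelVector, SimConfig, generate_corpus


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(
        ("s1", "s2", "s3"),
        ("taxA", "taxB", "taxC", "taxD"),
        np.array([[2, 3, 5, 0], [1, 0, 0, 9], [4, 4, 1, 1]]),
    )


@pytest.fixture
def tiny_labels(tiny_counts) -> LabelVector:
    return LabelVector(
        tiny_counts.subject_ids, ("Healthy", "Stress", "Healthy"), ("Healthy", "Stress")
    )


@pytest.fixture(scope="session")
def two_topic_corpus():
    """Two topics with disjoint taxon supports: an easy recovery target."""
    beta = np.zeros((2, 10))
    beta[0, :5] = 0.2
    beta[1, 5:] = 0.2
    cfg = SimConfig(M=100, B=10, T=2, lam=300, alpha=0.1, beta=beta,
                    levels=("Healthy", "Stress"), seed=11)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def three_topic_corpus():
    """Well-separated three-topic corpus with noise-free labels."""
    cfg = SimConfig(M=60, B=30, T=3, lam=300, alpha=0.1, separation=0.5,
                    label_noise=0.0, seed=5)
    return generate_corpus(cfg)
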