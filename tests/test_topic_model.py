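"""Variational LDA: limits, determinism, bound monotonicity, inference."""

import itertools

import numpy as np
import pytest

from rfslda import CountTable, SimConfig, assign_topics, fit_lda, generate_corpus, infer_theta, perplexity


def _align_tv(beta_hat, beta_true):
    """Mean total variation after the best topic permutation."""
    T = beta_true.shape[0]
    return min(
        0.5 * np.abs(beta_hat[list(p)] - beta_true).sum(axis=1).mean()
        for p in itertools.permutations(range(T))
    )


def test_single_topic_limit(tiny_counts):
    m = fit_lda(tiny_counts, T=1, alpha=1.0, seed=0)
    np.testing.assert_allclose(m.theta, 1.0)
    pooled = tiny_counts.counts.sum(axis=0) / tiny_counts.counts.sum()
    assert 0.5 * np.abs(m.beta[0] - pooled).sum() <= 0.01


def test_fit_deterministic_given_seed(three_topic_corpus):
    a = fit_lda(three_topic_corpus.counts, 3, seed=7)
    b = fit_lda(three_topic_corpus.counts, 3, seed=7)
    np.testing.assert_array_equal(a.theta, b.theta)
    np.testing.assert_array_equal(a.beta, b.beta)


def test_rows_stochastic_and_bound_monotone(three_topic_corpus):
    m = fit_lda(three_topic_corpus.counts, 3, seed=1)
    np.testing.assert_allclose(m.theta.sum(axis=1), 1.0, atol=1e-8)
    np.testing.assert_allclose(m.beta.sum(axis=1), 1.0, atol=1e-8)
    b = np.array(m.bounds)
    assert (np.diff(b) >= -1e-6 * np.abs(b[:-1])).all()


def test_recovers_disjoint_support_topics(two_topic_corpus):
    m = fit_lda(two_topic_corpus.counts, 2, seed=3)
    assert _align_tv(m.beta, two_topic_corpus.beta) <= 0.05


def test_zero_row_rejected():
    table = CountTable(("a", "b"), ("t1", "t2"), np.array([[1, 2], [0, 0]]))
    with pytest.raises(ValueError, match="positive total"):
        fit_lda(table, 2, seed=0)


def test_t_above_subjects_warns(tiny_counts):
    with pytest.warns(UserWarning, match="exceeds"):
        fit_lda(tiny_counts, T=5, alpha=1.0, seed=0)


def test_infer_theta_concentrates_on_exclusive_support(two_topic_corpus):
    m = fit_lda(two_topic_corpus.counts, 2, alpha=0.05, seed=3)
    # a held-out subject whose reads all lie in one topic's support
    topic0_support = np.argmax(m.beta[0]) == np.arange(10)
    probe = np.zeros((1, 10), dtype=int)
    probe[0, np.argmax(m.beta[0])] = 200
    held = CountTable(("probe",), two_topic_corpus.counts.taxon_names, probe)
    theta = infer_theta(m, held)
    assert theta.max() >= 0.9


def test_infer_theta_fold_in_consistency(three_topic_corpus):
    m = fit_lda(three_topic_corpus.counts, 3, seed=2)
    theta = infer_theta(m, three_topic_corpus.counts)
    tv = 0.5 * np.abs(theta - m.theta).sum(axis=1)
    assert tv.max() <= 0.05


def test_infer_theta_rejects_mismatch_and_zero_rows(three_topic_corpus, tiny_counts):
    m = fit_lda(three_topic_corpus.counts, 3, seed=2)
    with pytest.raises(ValueError, match="taxon"):
        infer_theta(m, tiny_counts)
    zero = CountTable(
        ("z",), three_topic_corpus.counts.taxon_names,
        np.zeros((1, three_topic_corpus.counts.n_taxa), dtype=int),
    )
    with pytest.raises(ValueError, match="positive total"):
        infer_theta(m, zero)


def test_perplexity_single_taxon_is_one():
    table = CountTable(("a", "b"), ("only",), np.array([[30], [12]]))
    m = fit_lda(table, T=1, alpha=1.0, seed=0)
    assert perplexity(m, table) == pytest.approx(1.0, abs=1e-6)


def test_perplexity_matches_token_oracle(two_topic_corpus):
    m = fit_lda(two_topic_corpus.counts, 2, seed=3)
    theta = infer_theta(m, two_topic_corpus.counts)
    X = two_topic_corpus.counts.counts
    loglik = sum(
        X[d, l] * np.log(theta[d] @ m.beta[:, l])
        for d in range(X.shape[0])
        for l in range(X.shape[1])
        if X[d, l]
    )
    oracle = np.exp(-loglik / X.sum())
    assert perplexity(m, two_topic_corpus.counts) == pytest.approx(oracle, abs=1e-6)


def test_perplexity_prefers_true_topic_count():
    """Mean held-out perplexity at the generating T=3 beats T=1 (5 seeds)."""
    wins = 0
    for seed in range(5):
        cfg = SimConfig(M=80, B=25, T=3, lam=200, alpha=0.1, separation=0.5, seed=seed)
        corpus = generate_corpus(cfg)
        train = corpus.counts.select_subjects(corpus.counts.subject_ids[:60])
        test = corpus.counts.select_subjects(corpus.counts.subject_ids[60:])
        p3 = perplexity(fit_lda(train, 3, seed=seed), test)
        p1 = perplexity(fit_lda(train, 1, seed=seed), test)
        wins += p3 <= p1
    assert wins == 5


def test_assign_topics_examples_and_oracle():
    a = assign_topics(np.array([[0.2, 0.4, 0.4]]))
    assert a.topics[0] == 1  # tie broken toward the lowest index
    assert assign_topics(np.array([[1.0, 0.0, 0.0]])).topics[0] == 0
    rng = np.random.default_rng(0)
    theta = rng.dirichlet(np.ones(4), size=100)
    got = assign_topics(theta).topics
    np.testing.assert_array_equal(got, theta.argmax(axis=1))


def test_assign_topics_rejects_empty():
    with pytest.raises(ValueError):
        assign_topics(np.zeros((0, 3)))


def test_fit_never_reads_labels():
    """Unsupervised contract: the fit signature admits no label input."""
    import inspect

    params = inspect.signature(fit_lda).parameters
    assert "labels" not in params


def test_agrees_with_sklearn_lda(two_topic_corpus):
    """Independent cross-check: sklearn's variational LDA recovers the same
    topic-taxon structure on an easy corpus."""
    from sklearn.decomposition import LatentDirichletAllocation

    m = fit_lda(two_topic_corpus.counts, 2, seed=3)
    sk = LatentDirichletAllocation(
        n_components=2, random_state=0, max_iter=50
    ).fit(two_topic_corpus.counts.counts)
    sk_beta = sk.components_ / sk.components_.sum(axis=1, keepdims=True)
    assert _align_tv(m.beta, sk_beta) <= 0.05
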