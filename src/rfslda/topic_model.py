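"""Latent Dirichlet allocation on taxon count tables.

Each subject is a "document" whose tokens are individual 16S reads; a topic
is a latent sub-community, i.e. a probability distribution over taxa.  The
generative model: theta_d ~ Dir(alpha) (symmetric), each read's topic
z ~ Mult(theta_d) and its taxon w ~ Mult(beta_z).  The total read count per
subject is ancillary to (theta, beta) and is not modelled at fit time.

Fitting is batch variational EM with a mean-field posterior
q(theta_d) = Dir(gamma_d), q(z) factorized per (subject, taxon).  beta is a
MAP point estimate under a symmetric Dirichlet(eta) smoothing prior so that
no entry is exactly zero (required for finite perplexity).  Every coordinate
update maximizes the (penalized) evidence lower bound, so the per-sweep bound
recorded in the fit metadata is non-decreasing.  The symmetric alpha can be
held fixed or estimated by a safeguarded Newton step each sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, polygamma, psi

from .io_interface import CountTable

__all__ = [
    "TopicModel",
    "TopicAssignment",
    "fit_lda",
    "infer_theta",
    "perplexity",
    "assign_topics",
]

_E_STEP_ITER = 60
_E_STEP_TOL = 1e-8


@dataclass(frozen=True)
class TopicModel:
    """Fitted LDA: per-subject topic proportions and per-topic taxon
    distributions, both row-stochastic."""

    T: int
    taxon_names: tuple[str, ...]
    theta: np.ndarray  # M x T
    beta: np.ndarray  # T x B0
    alpha: float
    eta: float
    method: str = "vem"
    n_iter: int = 0
    bounds: tuple[float, ...] = ()  # per-sweep variational bound
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("theta", "beta"):
            m = getattr(self, name)
            if (m < 0).any():
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError(f"{name} rows must sum to 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class TopicAssignment:
    """Hard per-subject topic labels (argmax of theta, lowest index on ties)."""

    topics: np.ndarray  # values in 0..T-1
    theta: np.ndarray


def _e_step(
    X: np.ndarray, log_beta: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-field updates for (gamma, phi) with beta fixed.

    Returns gamma (M x T) and phi (M x T x B), where phi[d, :, l] is the
    topic-responsibility of taxon l's reads in subject d.
    """
    M, B = X.shape
    T = log_beta.shape[0]
    gamma = np.full((M, T), alpha) + X.sum(axis=1, keepdims=True) / T
    phi = np.empty((M, T, B))
    for _ in range(_E_STEP_ITER):
        elog = psi(gamma) - psi(gamma.sum(axis=1, keepdims=True))
        np.add(elog[:, :, None], log_beta[None, :, :], out=phi)
        phi -= phi.max(axis=1, keepdims=True)
        np.exp(phi, out=phi)
        phi /= phi.sum(axis=1, keepdims=True)
        gamma_new = alpha + np.einsum("dl,dtl->dt", X, phi)
        delta = np.abs(gamma_new - gamma).mean()
        gamma = gamma_new
        if delta < _E_STEP_TOL:
            break
    return gamma, phi


def _bound(
    X: np.ndarray,
    gamma: np.ndarray,
    phi: np.ndarray,
    log_beta: np.ndarray,
    alpha: float,
    eta: float,
) -> float:
    """Penalized evidence lower bound (beta treated as a MAP point)."""
    M, T = gamma.shape
    elog = psi(gamma) - psi(gamma.sum(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        log_phi = np.where(phi > 0, np.log(phi), 0.0)
    # token terms: E[log p(w|z)] + E[log p(z|theta)] - E[log q(z)]
    tok = np.einsum(
        "dl,dtl->", X, phi * (elog[:, :, None] + log_beta[None, :, :] - log_phi)
    )
    # theta prior and entropy of q(theta)
    prior = M * (gammaln(T * alpha) - T * gammaln(alpha)) + (alpha - 1.0) * elog.sum()
    entropy = (
        gammaln(gamma.sum(axis=1)).sum()
        - gammaln(gamma).sum()
        + ((gamma - 1.0) * elog).sum()
    )
    penalty = (eta - 1.0) * log_beta.sum()
    return float(tok + prior - entropy + penalty)


def _alpha_objective(alpha: float, elog_sum: float, M: int, T: int) -> float:
    return M * (gammaln(T * alpha) - T * gammaln(alpha)) + (alpha - 1.0) * elog_sum


def _update_alpha(alpha: float, elog: np.ndarray, max_newton: int = 20) -> float:
    """Safeguarded Newton ascent on the symmetric Dirichlet concentration."""
    M, T = elog.shape
    s = float(elog.sum())
    f0 = _alpha_objective(alpha, s, M, T)
    for _ in range(max_newton):
        g = M * T * (psi(T * alpha) - psi(alpha)) + s
        h = M * T * (T * polygamma(1, T * alpha) - polygamma(1, alpha))
        if h == 0:
            break
        step = g / h
        new = alpha - step
        # backtrack to preserve positivity and monotone ascent
        for _ in range(30):
            if new > 1e-6 and _alpha_objective(new, s, M, T) >= f0:
                break
            step /= 2.0
            new = alpha - step
        else:
            break
        if abs(new - alpha) < 1e-8 * alpha:
            alpha = new
            break
        alpha = new
        f0 = _alpha_objective(alpha, s, M, T)
    return float(alpha)


def fit_lda(
    counts: CountTable,
    T: int,
    alpha: float | str = "estimate",
    seed: int | None = 0,
    eta: float = 0.1,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> TopicModel:
    """Fit the LDA model by batch variational EM.

    Parameters
    ----------
    counts
        Subjects × taxa integer table; every row total must be positive.
    T
        Number of latent topics (sub-communities).
    alpha
        Symmetric Dirichlet concentration for theta.  ``"estimate"`` starts
        at 50/T and re-estimates each sweep; a float holds it fixed.
    seed
        Controls the random beta initialization only; the rest of the fit is
        deterministic.
    eta
        Symmetric Dirichlet smoothing on beta (keeps all entries positive).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    X = counts.counts.astype(float)
    M, B = X.shape
    if (X.sum(axis=1) == 0).any():
        raise ValueError("every subject must have a positive total count")
    if T > M:
        import warnings

        warnings.warn(f"T={T} exceeds the number of subjects M={M}", stacklevel=2)

    estimate_alpha = alpha == "estimate"
    a = 50.0 / T if estimate_alpha else float(alpha)
    if a <= 0:
        raise ValueError("alpha must be positive")

    rng = np.random.default_rng(seed)
    # random positive init, mildly seeded by the empirical taxon frequencies
    beta = rng.gamma(1.0, 1.0, size=(T, B)) + 1e-3
    beta *= X.sum(axis=0) / X.sum() + 1e-3
    beta /= beta.sum(axis=1, keepdims=True)

    bounds: list[float] = []
    gamma = None
    for sweep in range(max_iter):
        log_beta = np.log(beta)
        gamma, phi = _e_step(X, log_beta, a)
        # M-step: MAP beta under Dirichlet(eta)
        beta = eta + np.einsum("dl,dtl->tl", X, phi)
        beta /= beta.sum(axis=1, keepdims=True)
        if estimate_alpha and T > 1:
            elog = psi(gamma) - psi(gamma.sum(axis=1, keepdims=True))
            a = _update_alpha(a, elog)
        bounds.append(_bound(X, gamma, phi, np.log(beta), a, eta))
        if sweep > 0 and abs(bounds[-1] - bounds[-2]) < tol * abs(bounds[-2]):
            break
    theta = gamma / gamma.sum(axis=1, keepdims=True)
    return TopicModel(
        T=T,
        taxon_names=counts.taxon_names,
        theta=theta,
        beta=beta,
        alpha=float(a),
        eta=eta,
        method="vem",
        n_iter=len(bounds),
        bounds=tuple(bounds),
        seed=seed,
    )


def infer_theta(model: TopicModel, counts: CountTable) -> np.ndarray:
    """Fold-in inference: per-subject topic proportions with beta held fixed.

    Deterministic (no randomness in the mean-field E-step)."""
    if counts.taxon_names != model.taxon_names:
        raise ValueError("taxon names do not match the fitted model")
    X = counts.counts.astype(float)
    if (X.sum(axis=1) == 0).any():
        raise ValueError("every subject must have a positive total count")
    gamma, _ = _e_step(X, np.log(model.beta), model.alpha)
    return gamma / gamma.sum(axis=1, keepdims=True)


def perplexity(model: TopicModel, counts: CountTable) -> float:
    """exp(-log-likelihood / total reads) under each subject's inferred
    topic mixture (plug-in theta, beta fixed)."""
    theta = infer_theta(model, counts)
    X = counts.counts.astype(float)
    mix = theta @ model.beta  # M x B per-read taxon probabilities
    loglik = float((X * np.log(mix)).sum())
    return float(np.exp(-loglik / X.sum()))


def assign_topics(theta: np.ndarray) -> TopicAssignment:
    """Hard topic label per subject: argmax of the proportion row, ties
    broken toward the lowest topic index."""
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] == 0:
        raise ValueError("theta must be a non-empty 2-D matrix")
    if not np.allclose(theta.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("theta rows must sum to 1")
    return TopicAssignment(topics=theta.argmax(axis=1), theta=theta)
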