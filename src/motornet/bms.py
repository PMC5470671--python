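"""Group-level Bayesian model selection from per-subject free energies.

Fixed-effects (FFX) comparison assumes every subject uses the same
model: log evidences sum over subjects and the posterior is their
softmax.  Random-effects (RFX) comparison treats the model as a random
quantity in the population: a variational scheme estimates a Dirichlet
posterior over model frequencies, and the exceedance probability of a
model is the posterior probability that it is the most frequent one,
estimated by Monte-Carlo sampling of the Dirichlet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, logsumexp

__all__ = ["BMSResult", "ffx_compare", "rfx_compare", "best_model_counts"]


@dataclass
class BMSResult:
    """Dirichlet posterior over model frequencies and derived quantities."""

    dirichlet_alpha: np.ndarray
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray
    subject_posteriors: np.ndarray   # subjects x models assignment probabilities
    n_samples: int


def _check_evidence(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] < 2:
        raise ValueError("evidence matrix must be subjects x models with >= 2 models")
    if not np.all(np.isfinite(F)):
        raise ValueError("evidence matrix must be finite")
    return F


def ffx_compare(F: np.ndarray) -> np.ndarray:
    """Fixed-effects posterior model probabilities (softmax of summed F)."""
    F = _check_evidence(F)
    s = F.sum(axis=0)
    return np.exp(s - logsumexp(s))


def rfx_compare(
    F: np.ndarray,
    seed: int | None = 0,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> BMSResult:
    """Random-effects model selection (variational Dirichlet scheme).

    Iterates subject-wise model assignment posteriors against the
    Dirichlet concentration until convergence, starting from a uniform
    prior ``alpha0`` per model, then estimates exceedance probabilities
    from ``n_samples`` Dirichlet draws.
    """
    F = _check_evidence(F)
    n_sub, n_mod = F.shape
    alpha = np.full(n_mod, alpha0, dtype=float)
    for _ in range(max_iter):
        alpha_prev = alpha.copy()
        log_u = F + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        u = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha - alpha_prev)) < tol:
            break
    else:
        raise RuntimeError(
            f"RFX scheme did not converge in {max_iter} iterations; "
            f"last alpha = {alpha}"
        )
    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    exceed = np.bincount(winners, minlength=n_mod) / n_samples
    return BMSResult(
        dirichlet_alpha=alpha,
        expected_prob=expected,
        exceedance_prob=exceed,
        subject_posteriors=u,
        n_samples=n_samples,
    )


def best_model_counts(F: np.ndarray) -> np.ndarray:
    """Per-model count of subjects for which it has the highest evidence."""
    F = _check_evidence(F)
    return np.bincount(np.argmax(F, axis=1), minlength=F.shape[1])
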