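"""Random-effects Bayesian model selection.

Given per-subject log model evidences, a variational Dirichlet scheme
estimates the population frequencies of the candidate models; from the
Dirichlet posterior come exceedance probabilities (EP), the Bayesian
omnibus risk (BOR — the posterior probability that all model frequencies
are indistinguishable), and the protected exceedance probability

    PXP_k = EP_k * (1 - BOR) + BOR / K,

which shrinks the EPs toward uniform by exactly the probability that
the comparison is uninformative.  Subject-level log evidence is
approximated from each subject's DIC contribution as -DIC/2.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp

from .hba_fit import DicResult

__all__ = [
    "BmsResult",
    "subject_evidence",
    "vb_bms",
    "exceedance_prob",
    "protected_pxp",
]


def subject_evidence(*dic_results: DicResult) -> np.ndarray:
    """Per-subject log evidence matrix (subjects x models) from DIC.

    Uses the approximation log evidence ~ -DIC_subject / 2, with each
    subject's DIC built from that subject's likelihood contribution and
    subject-level draws.  All models must be fitted on the same subjects.
    """
    if len(dic_results) < 2:
        raise ValueError("need at least two models")
    ids = dic_results[0].subject_ids
    for r in dic_results[1:]:
        if r.subject_ids != ids:
            raise ValueError("models fitted on different subject sets")
    return np.column_stack([-0.5 * r.subject_dic for r in dic_results])


def _check_evidence(log_evidence: np.ndarray) -> np.ndarray:
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("need a (subjects >= 2, models >= 2) evidence matrix")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    return L


def vb_bms(log_evidence: np.ndarray, alpha0: float = 1.0,
           tol: float = 1e-8, max_iter: int = 10_000):
    """Variational Dirichlet update for random-effects model frequencies.

    Iterates subject responsibilities proportional to
    ``exp(log evidence + digamma(alpha_k) - digamma(sum alpha))`` and
    concentration updates ``alpha_k = alpha0 + sum responsibilities``
    until the concentrations move less than ``tol``.

    Returns ``(alpha, expected_frequencies, responsibilities)``.
    """
    L = _check_evidence(log_evidence)
    n, k = L.shape
    alpha = np.full(k, alpha0 + n / k)
    for _ in range(max_iter):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        z = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + z.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            return alpha_new, alpha_new / alpha_new.sum(), z
        alpha = alpha_new
    raise RuntimeError(
        f"variational BMS did not converge in {max_iter} iterations "
        f"(last alpha = {alpha})")


def exceedance_prob(alpha: np.ndarray, n_draws: int = 1_000_000,
                    seed: int = 0) -> np.ndarray:
    """P(model k has the largest frequency) under Dirichlet(alpha).

    For two models the answer is exact via the Beta distribution;
    for more, seeded Monte Carlo over Dirichlet draws.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or alpha.size < 2:
        raise ValueError("need at least two concentrations")
    if alpha.size == 2:
        # P(r1 > 0.5) with r1 ~ Beta(a1, a2)
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=alpha.size) / n_draws


def _dirichlet_free_energy(L, z, alpha, alpha0):
    """Variational free energy of the random-frequencies hypothesis."""
    elog_r = digamma(alpha) - digamma(alpha.sum())
    a0 = np.full_like(alpha, alpha0)
    f = (z * L).sum()
    f += ((z.sum(axis=0) + a0 - alpha) * elog_r).sum()
    f += gammaln(a0.sum()) - gammaln(a0).sum()
    f -= gammaln(alpha.sum()) - gammaln(alpha).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        f -= np.where(z > 0, z * np.log(z), 0.0).sum()
    return float(f)


@dataclasses.dataclass(frozen=True)
class BmsResult:
    alpha: np.ndarray
    frequencies: np.ndarray
    ep: np.ndarray
    bor: float
    pxp: np.ndarray
    responsibilities: np.ndarray


def protected_pxp(log_evidence: np.ndarray, alpha0: float = 1.0,
                  seed: int = 0) -> BmsResult:
    """Exceedance probabilities protected by the Bayesian omnibus risk.

    BOR compares the free energy of the null hypothesis (all model
    frequencies fixed at 1/K) with that of the fitted Dirichlet model;
    PXP blends EP toward uniform by the BOR.
    """
    L = _check_evidence(log_evidence)
    n, k = L.shape
    alpha, freq, z = vb_bms(L, alpha0=alpha0)
    ep = exceedance_prob(alpha, seed=seed)
    f1 = _dirichlet_free_energy(L, z, alpha, alpha0)
    f0 = float((logsumexp(L, axis=1) - np.log(k)).sum())
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = ep * (1.0 - bor) + bor / k
    return BmsResult(alpha=alpha, frequencies=freq, ep=ep, bor=bor,
                     pxp=pxp, responsibilities=z)
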