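"""Hierarchical Bayesian estimation of the prospect-theory model.

Subject-level parameters (alpha, lam, tau — plus alpha_plus/alpha_minus in
the dual-risk variant) are drawn from group-level normal distributions
restricted to positive values (zero-truncated normals).  Group means have
Normal(0, 1) priors and group standard deviations half-Cauchy(0, 5)
priors.  Sampling is performed on an unconstrained scale (log for the
subject parameters and group sds) with the Jacobian included, using a
vectorised adaptive Metropolis-within-Gibbs scheme: each subject-level
coordinate is updated for all subjects simultaneously with per-coordinate
random-walk steps adapted during warmup, and each group (mean, sd) pair
is updated jointly.  Defaults mirror four chains with 12000 warmup
iterations and 6000 retained draws per chain (24000 total).

Also provided: split-chain Gelman-Rubin R-hat, per-subject maximum
likelihood estimation, and the deviance information criterion with its
per-subject decomposition.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr

from .prospect_model import ChoiceDataset, PTParams, PTParamsDual

__all__ = [
    "HierarchicalPrior",
    "PosteriorDraws",
    "FitResult",
    "SINGLE_ALPHA",
    "DUAL_ALPHA",
    "NO_LOSS_AVERSION",
    "stack_choice_data",
    "log_joint",
    "run_mcmc",
    "rhat",
    "split_rhat",
    "fit_mle",
    "MleResult",
    "dic",
    "DicResult",
    "fit_hba",
]

_LOGIT_CAP = 500.0
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclasses.dataclass(frozen=True)
class HierarchicalPrior:
    """Group-level priors: mu ~ Normal(loc, scale), sigma ~ half-Cauchy(scale)."""

    mu_loc: float = 0.0
    mu_scale: float = 1.0
    sigma_scale: float = 5.0


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Which subject-level parameters a choice model carries.

    ``kinds`` tags each column with the cheapest way to refresh the
    likelihood when it changes: ``"alpha"`` forces recomputation of the
    power terms, ``"lam"`` only re-weights the loss branch, ``"tau"``
    only rescales the logistic argument.
    """

    name: str
    param_names: tuple[str, ...]
    kinds: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.param_names)

    def unpack(self, theta: np.ndarray):
        """theta (n, k) -> (alpha_plus, alpha_minus, lam, tau), each (n,)."""
        if self.name == "single_alpha":
            a, lam, tau = theta[:, 0], theta[:, 1], theta[:, 2]
            return a, a, lam, tau
        if self.name == "no_loss_aversion":
            a, tau = theta[:, 0], theta[:, 1]
            return a, a, np.ones_like(a), tau
        ap, am, lam, tau = theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3]
        return ap, am, lam, tau

    def to_params(self, row: np.ndarray):
        if self.name == "single_alpha":
            return PTParams(*row)
        if self.name == "no_loss_aversion":
            return PTParams(row[0], 1.0, row[1])
        return PTParamsDual(*row)


SINGLE_ALPHA = ModelSpec("single_alpha", ("alpha", "lam", "tau"),
                         ("alpha", "lam", "tau"))
DUAL_ALPHA = ModelSpec("dual_alpha", ("alpha_plus", "alpha_minus", "lam", "tau"),
                       ("alpha", "alpha", "lam", "tau"))
#: Restriction with loss aversion pinned at 1 (losses weighted like gains);
#: useful as a mis-specified comparator in model-recovery checks.
NO_LOSS_AVERSION = ModelSpec("no_loss_aversion", ("alpha", "tau"),
                             ("alpha", "tau"))


class StackedChoices:
    """Rectangularised multi-subject choice data for fast likelihoods.

    Arrays have shape (n_subjects, max_trials); ``mask`` marks real
    trials.  Only modeled trials (non-catch, answered) enter.
    """

    def __init__(self, data: ChoiceDataset):
        df = data.modeled().df
        if len(df) == 0:
            raise ValueError("no modeled trials")
        self.subject_ids = list(pd.unique(df["subject_id"]))
        groups = [df[df["subject_id"] == s] for s in self.subject_ids]
        n = len(groups)
        tmax = max(len(g) for g in groups)
        self.g1 = np.zeros((n, tmax))
        self.g2 = np.zeros((n, tmax))
        self.sure = np.zeros((n, tmax))
        self.sign = np.zeros((n, tmax))  # +1 chose gamble, -1 chose sure, 0 pad
        for i, g in enumerate(groups):
            t = len(g)
            self.g1[i, :t] = g["gamble_out1"].to_numpy()
            self.g2[i, :t] = g["gamble_out2"].to_numpy()
            self.sure[i, :t] = g["sure"].to_numpy()
            self.sign[i, :t] = np.where(g["choice"].to_numpy() == 1, 1.0, -1.0)
        self.mask = self.sign != 0
        with np.errstate(divide="ignore"):
            self.la1 = np.log(np.abs(self.g1))
            self.la2 = np.log(np.abs(self.g2))
            self.las = np.log(np.abs(self.sure))
        self.pos1 = self.g1 >= 0
        self.pos2 = self.g2 >= 0
        self.poss = self.sure >= 0

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def powers(self, ap: np.ndarray, am: np.ndarray):
        """|x|**alpha for each trial outcome, with the domain exponent."""
        ap = ap[:, None]
        am = am[:, None]
        with np.errstate(invalid="ignore", over="ignore"):
            p1 = np.exp(np.where(self.pos1, ap, am) * self.la1)
            p2 = np.exp(np.where(self.pos2, ap, am) * self.la2)
            ps = np.exp(np.where(self.poss, ap, am) * self.las)
        return p1, p2, ps

    def du(self, pows, lam: np.ndarray):
        """u_gamble - u_sure from cached power terms."""
        p1, p2, ps = pows
        lam = lam[:, None]
        with np.errstate(invalid="ignore", over="ignore"):
            u1 = np.where(self.pos1, p1, -lam * p1)
            u2 = np.where(self.pos2, p2, -lam * p2)
            us = np.where(self.poss, ps, -lam * ps)
            return 0.5 * (u1 + u2) - us

    def loglik_from_du(self, du: np.ndarray, tau: np.ndarray) -> np.ndarray:
        """Per-subject log-likelihood (n,); overflowed utilities (inf - inf
        from extreme proposal states) yield -inf, a rejected state."""
        with np.errstate(invalid="ignore", over="ignore"):
            x = np.clip(self.sign * tau[:, None] * du, -_LOGIT_CAP, _LOGIT_CAP)
            terms = -np.logaddexp(0.0, -x)
            out = np.where(self.mask, terms, 0.0).sum(axis=1)
        return np.where(np.isfinite(out), out, -np.inf)

    def loglik(self, theta: np.ndarray, model: ModelSpec) -> np.ndarray:
        ap, am, lam, tau = model.unpack(theta)
        du = self.du(self.powers(ap, am), lam)
        return self.loglik_from_du(du, tau)


def stack_choice_data(data: ChoiceDataset) -> StackedChoices:
    """Prepare a (possibly multi-subject) dataset for hierarchical fitting."""
    return StackedChoices(data)


# ---------------------------------------------------------------------------
# densities


def _truncnorm_logpdf(theta, mu, sigma):
    """log density of Normal(mu, sigma) truncated to (0, inf), at theta > 0."""
    z = (theta - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - _HALF_LOG_2PI - log_ndtr(mu / sigma)


def _half_cauchy_logpdf(sigma, scale):
    return np.log(2.0 / np.pi) - np.log(scale) - np.log1p((sigma / scale) ** 2)


def _normal_logpdf(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * z * z - np.log(scale) - _HALF_LOG_2PI


def _unflatten(vec: np.ndarray, n: int, k: int):
    mu = vec[:k]
    log_sigma = vec[k:2 * k]
    z = vec[2 * k:].reshape(n, k)
    return mu, log_sigma, z


def log_joint(vec: np.ndarray, data: StackedChoices,
              prior: HierarchicalPrior = HierarchicalPrior(),
              model: ModelSpec = SINGLE_ALPHA) -> float:
    """Unnormalised log posterior density on the unconstrained scale.

    Parameter vector layout: group means ``mu`` (k), log group sds (k),
    then per-subject log parameters row-major (n, k).  Log-scale
    parameters carry their Jacobian terms; any non-finite density
    evaluates to ``-inf`` (a rejected state), never NaN.
    """
    vec = np.asarray(vec, dtype=float)
    n, k = data.n_subjects, model.k
    if vec.shape != (2 * k + n * k,):
        raise ValueError(f"expected parameter vector of length {2 * k + n * k}")
    if not np.all(np.isfinite(vec)):
        return -np.inf
    mu, log_sigma, z = _unflatten(vec, n, k)
    sigma = np.exp(log_sigma)
    theta = np.exp(z)
    lp = _normal_logpdf(mu, prior.mu_loc, prior.mu_scale).sum()
    lp += (_half_cauchy_logpdf(sigma, prior.sigma_scale) + log_sigma).sum()
    lp += (_truncnorm_logpdf(theta, mu[None, :], sigma[None, :]) + z).sum()
    lp += data.loglik(theta, model).sum()
    return float(lp) if np.isfinite(lp) else -np.inf


# ---------------------------------------------------------------------------
# sampler


@dataclasses.dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws, indexed (chain, draw, parameter)."""

    draws: np.ndarray
    param_names: list[str]
    model: ModelSpec
    subject_ids: list

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def get(self, name: str) -> np.ndarray:
        """(chains, draws) array for one named parameter."""
        return self.draws[:, :, self.param_names.index(name)]

    def subject_theta(self) -> np.ndarray:
        """Subject-level draws, shape (chain*draw, n_subjects, k)."""
        k = self.model.k
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        return flat[:, 2 * k:].reshape(-1, self.n_subjects, k)

    def to_frame(self) -> pd.DataFrame:
        c, d, p = self.draws.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), d * p),
            "iter": np.tile(np.repeat(np.arange(d), p), c),
            "parameter": np.tile(self.param_names, c * d),
            "value": self.draws.ravel(),
        })


def _param_names(model: ModelSpec, subject_ids) -> list[str]:
    names = [f"mu_{p}" for p in model.param_names]
    names += [f"sigma_{p}" for p in model.param_names]
    for i in range(len(subject_ids)):
        names += [f"{p}[{i}]" for p in model.param_names]
    return names


def _init_state(rng, n, k, data, model, prior, max_tries=10):
    for _ in range(max_tries):
        mu = np.abs(1.0 + 0.3 * rng.standard_normal(k))
        log_sigma = np.log(0.5) + 0.2 * rng.standard_normal(k)
        z = np.log(np.maximum(mu, 0.3))[None, :] + 0.2 * rng.standard_normal((n, k))
        vec = np.concatenate([mu, log_sigma, z.ravel()])
        if np.isfinite(log_joint(vec, data, prior, model)):
            return mu, log_sigma, z
    raise RuntimeError("could not find a finite initial state")


def _run_chain(data: StackedChoices, prior: HierarchicalPrior, model: ModelSpec,
               n_warmup: int, n_samples: int, thin: int,
               rng: np.random.Generator) -> np.ndarray:
    n, k = data.n_subjects, model.k
    mu, log_sigma, z = _init_state(rng, n, k, data, model, prior)
    sigma = np.exp(log_sigma)
    theta = np.exp(z)

    ap, am, lam, tau = model.unpack(theta)
    pows = data.powers(ap, am)
    du = data.du(pows, lam)
    ll = data.loglik_from_du(du, tau)

    z_step = np.full((n, k), 0.25)
    g_step = np.full(k, 0.15)
    joint_scale = np.full(n, 0.5)
    z_acc = np.zeros((n, k))
    g_acc = np.zeros(k)
    joint_acc = np.zeros(n)
    batch = 50

    # running moments of z per subject, for the adapted joint proposal
    mom_count = 0
    mom_mean = np.zeros((n, k))
    mom_m2 = np.zeros((n, k, k))
    chol = np.broadcast_to(0.1 * np.eye(k), (n, k, k)).copy()

    out = np.empty((n_samples, 2 * k + n * k))
    total = n_warmup + n_samples * thin

    def subject_prior_rowsum(z_mat, theta_mat):
        return (_truncnorm_logpdf(theta_mat, mu[None, :], sigma[None, :])
                + z_mat).sum(axis=1)

    for it in range(total):
        warm = it < n_warmup
        # --- subject-level coordinate updates (vectorised over subjects)
        for j in range(k):
            z_prop = z.copy()
            z_prop[:, j] = z[:, j] + z_step[:, j] * rng.standard_normal(n)
            theta_prop = theta.copy()
            theta_prop[:, j] = np.exp(z_prop[:, j])
            kind = model.kinds[j]
            apP, amP, lamP, tauP = model.unpack(theta_prop)
            if kind == "alpha":
                pows_prop = data.powers(apP, amP)
                du_prop = data.du(pows_prop, lamP)
            elif kind == "lam":
                pows_prop = pows
                du_prop = data.du(pows, lamP)
            else:  # tau
                pows_prop = pows
                du_prop = du
            ll_prop = data.loglik_from_du(du_prop, tauP)
            d_prior = (
                _truncnorm_logpdf(theta_prop[:, j], mu[j], sigma[j]) + z_prop[:, j]
                - _truncnorm_logpdf(theta[:, j], mu[j], sigma[j]) - z[:, j]
            )
            delta = ll_prop - ll + d_prior
            accept = np.log(rng.random(n)) < delta
            if np.any(accept):
                z[accept, j] = z_prop[accept, j]
                theta[accept, j] = theta_prop[accept, j]
                ll = np.where(accept, ll_prop, ll)
                if kind == "alpha":
                    rows = accept
                    for cur, new in zip(pows, pows_prop):
                        cur[rows] = new[rows]
                    du[rows] = du_prop[rows]
                elif kind == "lam":
                    du[accept] = du_prop[accept]
            if warm:
                z_acc[:, j] += accept

        # --- joint subject updates along the adapted posterior covariance
        # (alpha and lam trade off within subject; coordinate moves alone
        # crawl along that ridge)
        for _ in range(2):
            eps = rng.standard_normal((n, k))
            z_prop = z + joint_scale[:, None] * np.einsum("nij,nj->ni", chol, eps)
            theta_prop = np.exp(z_prop)
            apP, amP, lamP, tauP = model.unpack(theta_prop)
            pows_prop = data.powers(apP, amP)
            du_prop = data.du(pows_prop, lamP)
            ll_prop = data.loglik_from_du(du_prop, tauP)
            delta = (ll_prop - ll
                     + subject_prior_rowsum(z_prop, theta_prop)
                     - subject_prior_rowsum(z, theta))
            accept = np.log(rng.random(n)) < delta
            if np.any(accept):
                z[accept] = z_prop[accept]
                theta[accept] = theta_prop[accept]
                ll = np.where(accept, ll_prop, ll)
                for cur, new in zip(pows, pows_prop):
                    cur[accept] = new[accept]
                du[accept] = du_prop[accept]
            if warm:
                joint_acc += accept
        if warm:
            if it == n_warmup // 3:
                # drop the early transient from the covariance estimate
                mom_count = 0
                mom_mean[:] = 0.0
                mom_m2[:] = 0.0
            mom_count += 1
            d1 = z - mom_mean
            mom_mean += d1 / mom_count
            mom_m2 += np.einsum("ni,nj->nij", d1, z - mom_mean)
            if mom_count > 200 and (it + 1) % 200 == 0:
                cov = mom_m2 / (mom_count - 1) + 1e-6 * np.eye(k)
                chol = np.linalg.cholesky(cov)

        # --- group-level joint (mu, log sigma) updates per parameter
        # (cheap: no likelihood term; several sweeps per iteration)
        for _ in range(3):
            for j in range(k):
                mu_p = mu[j] + g_step[j] * rng.standard_normal()
                ls_p = log_sigma[j] + g_step[j] * rng.standard_normal()
                sig_p = np.exp(ls_p)
                cur = (_normal_logpdf(mu[j], prior.mu_loc, prior.mu_scale)
                       + _half_cauchy_logpdf(sigma[j], prior.sigma_scale)
                       + log_sigma[j]
                       + _truncnorm_logpdf(theta[:, j], mu[j], sigma[j]).sum())
                prop = (_normal_logpdf(mu_p, prior.mu_loc, prior.mu_scale)
                        + _half_cauchy_logpdf(sig_p, prior.sigma_scale) + ls_p
                        + _truncnorm_logpdf(theta[:, j], mu_p, sig_p).sum())
                if np.log(rng.random()) < prop - cur:
                    mu[j], log_sigma[j], sigma[j] = mu_p, ls_p, sig_p
                    if warm:
                        g_acc[j] += 1

        # --- warmup step-size adaptation (Robbins-Monro style batches)
        if warm and (it + 1) % batch == 0:
            eta = min(0.1, ((it + 1) // batch) ** -0.5)
            z_step *= np.exp(eta * (z_acc / batch - 0.44))
            g_step *= np.exp(eta * (g_acc / (3 * batch) - 0.30))
            joint_scale *= np.exp(eta * (joint_acc / (2 * batch) - 0.30))
            z_acc[:] = 0.0
            g_acc[:] = 0.0
            joint_acc[:] = 0.0

        if not warm and (it - n_warmup) % thin == thin - 1:
            out[(it - n_warmup) // thin] = np.concatenate(
                [mu, np.exp(log_sigma), theta.ravel()])
    return out


def run_mcmc(data: StackedChoices | ChoiceDataset,
             prior: HierarchicalPrior = HierarchicalPrior(),
             model: ModelSpec = SINGLE_ALPHA,
             n_chains: int = 4, n_warmup: int = 12000, n_samples: int = 6000,
             thin: int = 4, seed: int = 0) -> PosteriorDraws:
    """Sample the hierarchical posterior; deterministic given ``seed``.

    Returns ``n_samples`` post-warmup draws per chain on the constrained
    scale (group means, group sds, then subject-level parameters),
    keeping every ``thin``-th iteration — a random-walk kernel needs the
    extra iterations to decorrelate the stored draws.
    """
    if isinstance(data, ChoiceDataset):
        data = stack_choice_data(data)
    if n_chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_chains)
    chains = [
        _run_chain(data, prior, model, n_warmup, n_samples, thin,
                   np.random.default_rng(child))
        for child in children
    ]
    return PosteriorDraws(
        draws=np.stack(chains),
        param_names=_param_names(model, data.subject_ids),
        model=model,
        subject_ids=data.subject_ids,
    )


# ---------------------------------------------------------------------------
# diagnostics


def split_rhat(x: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``x`` has shape (chains, draws); each chain is split in half before
    computing the between/within variance ratio.  Zero total variance
    (all chains constant) returns 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains >= 2, draws) array")
    half = x.shape[1] // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    chains = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, nn = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = nn * means.var(ddof=1)
    if w == 0.0:
        return 1.0
    var_plus = (nn - 1) / nn * w + b / nn
    return float(np.sqrt(var_plus / w))


def rhat(draws: PosteriorDraws, parameter: str | None = None):
    """R-hat for one named parameter, or a dict over all parameters."""
    if parameter is not None:
        return split_rhat(draws.get(parameter))
    return {name: split_rhat(draws.get(name)) for name in draws.param_names}


# ---------------------------------------------------------------------------
# maximum likelihood


@dataclasses.dataclass(frozen=True)
class MleResult:
    params: PTParams | PTParamsDual
    nll: float
    at_bound: bool


_MLE_BOUNDS = {"alpha": (0.05, 5.0), "alpha_plus": (0.05, 5.0),
               "alpha_minus": (0.05, 5.0), "lam": (0.05, 20.0),
               "tau": (1e-3, 50.0)}


def fit_mle(data: ChoiceDataset, model: ModelSpec = SINGLE_ALPHA,
            n_starts: int = 8, seed: int = 0) -> MleResult:
    """Multi-start bounded maximum-likelihood fit for a single subject.

    Minimises the negative log-likelihood on the log-parameter scale with
    L-BFGS-B.  Degenerate data (e.g. an all-sure chooser) returns the
    boundary solution with ``at_bound=True`` rather than raising.
    """
    stacked = stack_choice_data(data)
    if stacked.n_subjects != 1:
        raise ValueError("fit_mle expects a single subject's data")
    lo = np.log([_MLE_BOUNDS[p][0] for p in model.param_names])
    hi = np.log([_MLE_BOUNDS[p][1] for p in model.param_names])

    def nll(logp):
        theta = np.exp(logp)[None, :]
        return -float(stacked.loglik(theta, model)[0])

    rng = np.random.default_rng(seed)
    starts = [np.zeros(model.k)]
    starts += [np.clip(0.6 * rng.standard_normal(model.k), lo, hi)
               for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        if best is None or res.fun < best.fun:
            best = res
    at_bound = bool(np.any(best.x < lo + 1e-4) or np.any(best.x > hi - 1e-4))
    return MleResult(params=model.to_params(np.exp(best.x)),
                     nll=float(best.fun), at_bound=at_bound)


# ---------------------------------------------------------------------------
# DIC


@dataclasses.dataclass(frozen=True)
class DicResult:
    dic: float
    p_d: float
    mean_deviance: float
    subject_dic: np.ndarray
    subject_p_d: np.ndarray
    subject_mean_deviance: np.ndarray
    subject_ids: list


def dic(draws: PosteriorDraws, data: StackedChoices | ChoiceDataset,
        max_draws: int | None = 4000) -> DicResult:
    """Deviance information criterion with per-subject decomposition.

    ``Dbar`` is the posterior-mean deviance (-2 log likelihood averaged
    over draws, stride-thinned to at most ``max_draws`` for speed); the
    effective parameter count ``pD`` is ``Dbar`` minus the deviance at a
    plug-in estimate of the subject-level parameters; DIC = Dbar + pD.
    The plug-in is the posterior mean on the log (sampling) scale — the
    geometric mean on the constrained scale.  The arithmetic mean can
    fall outside curved posterior ridges (alpha/lambda/tau trade off
    multiplicatively), producing pathological negative pD.
    """
    if isinstance(data, ChoiceDataset):
        data = stack_choice_data(data)
    theta = draws.subject_theta()
    if max_draws is not None and theta.shape[0] > max_draws:
        stride = int(np.ceil(theta.shape[0] / max_draws))
        theta = theta[::stride]
    dev = np.zeros((theta.shape[0], data.n_subjects))
    for d in range(theta.shape[0]):
        dev[d] = -2.0 * data.loglik(theta[d], draws.model)
    dbar_i = dev.mean(axis=0)
    plug_in = np.exp(np.log(theta).mean(axis=0))
    dev_at_mean_i = -2.0 * data.loglik(plug_in, draws.model)
    pd_i = dbar_i - dev_at_mean_i
    dic_i = dbar_i + pd_i
    return DicResult(
        dic=float(dic_i.sum()), p_d=float(pd_i.sum()),
        mean_deviance=float(dbar_i.sum()),
        subject_dic=dic_i, subject_p_d=pd_i, subject_mean_deviance=dbar_i,
        subject_ids=list(draws.subject_ids),
    )


# ---------------------------------------------------------------------------
# high-level fit


@dataclasses.dataclass
class FitResult:
    """Posterior summaries from a hierarchical fit."""

    draws: PosteriorDraws
    subject_estimates: pd.DataFrame
    group_summary: dict
    rhat: dict
    dic: DicResult

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def converged(self, threshold: float = 1.01) -> bool:
        return self.max_rhat <= threshold

    def write(self, outdir: str | Path, stem: str = "fit") -> None:
        import json as _json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subject_estimates.to_csv(outdir / f"{stem}_subjects.csv", index=False)
        (outdir / f"{stem}_group.json").write_text(
            _json.dumps(self.group_summary, indent=2))
        pd.Series(self.rhat, name="rhat").rename_axis("parameter").to_csv(
            outdir / f"{stem}_rhat.csv")


def fit_hba(data: ChoiceDataset | StackedChoices,
            model: ModelSpec = SINGLE_ALPHA,
            prior: HierarchicalPrior = HierarchicalPrior(),
            n_chains: int = 4, n_warmup: int = 12000, n_samples: int = 6000,
            thin: int = 4, seed: int = 0,
            dic_max_draws: int | None = 4000) -> FitResult:
    """Run the hierarchical fit and summarise it.

    Subject point estimates are posterior means on the constrained
    scale; ``ln_lam`` is the natural log of the estimated loss aversion.
    """
    if isinstance(data, ChoiceDataset):
        data = stack_choice_data(data)
    draws = run_mcmc(data, prior=prior, model=model, n_chains=n_chains,
                     n_warmup=n_warmup, n_samples=n_samples, thin=thin,
                     seed=seed)
    theta = draws.subject_theta().mean(axis=0)  # (n, k)
    est = pd.DataFrame(theta, columns=list(model.param_names))
    est.insert(0, "subject_id", data.subject_ids)
    if "lam" in est.columns:
        est["ln_lam"] = np.log(est["lam"])
    group = {}
    for p in model.param_names:
        group[f"mu_{p}"] = float(draws.get(f"mu_{p}").mean())
        group[f"sigma_{p}"] = float(draws.get(f"sigma_{p}").mean())
    return FitResult(
        draws=draws,
        subject_estimates=est,
        group_summary=group,
        rhat=rhat(draws),
        dic=dic(draws, data, max_draws=dic_max_draws),
    )
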