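"""Hierarchical Bayesian inference for hyperbolic temporal discounting.

The model: an option of amount ``A`` (EUR) delayed by ``D`` days has
subjective value ``SV = A / (1 + k*D)`` (hyperbolic discounting with
participant-specific rate ``k``), and a binary choice between a larger-but-
later (LL) and a smaller-but-sooner (SS) option is made with softmax
probability ``p_LL = exp(SV_LL/beta) / (exp(SV_LL/beta) + exp(SV_SS/beta))``.
``beta`` is a temperature *divisor*: larger beta means noisier choice.

Participant-level parameters live on the log scale, ``log k`` and
``log beta``, drawn from group-specific normal distributions (one per
clinical group) whose means and precisions carry weakly informative
hyperpriors.  Posteriors are sampled with Metropolis-within-Gibbs:
conjugate normal-gamma updates for the group-level means/precisions and an
adaptive random-walk Metropolis step, vectorized across participants, for
the participant-level pairs.  Convergence is gated on split-R-hat and
effective sample size (via arviz).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize

from ._rng import substream

__all__ = [
    "subjective_value",
    "choice_probability",
    "MCMCConfig",
    "GroupPrior",
    "HierarchicalFit",
    "fit_hierarchical",
    "combine_and_refit",
    "summarize_log_k",
    "fit_mle",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when the sampler fails its split-R-hat / ESS gate."""


def subjective_value(A, k, D):
    """Hyperbolic subjective value ``A / (1 + k*D)``.

    ``A`` in EUR, ``k`` in 1/days, ``D`` in days.  Accepts scalars or arrays.
    """
    A, k, D = np.asarray(A, float), np.asarray(k, float), np.asarray(D, float)
    if np.any(A <= 0):
        raise ValueError("amount must be > 0")
    if np.any(k < 0) or np.any(D < 0):
        raise ValueError("k and D must be >= 0")
    out = A / (1.0 + k * D)
    return float(out) if out.ndim == 0 else out


def choice_probability(sv_ll, sv_ss, beta):
    """Softmax probability of choosing the larger-but-later option.

    Computed in the overflow-safe logistic form
    ``1 / (1 + exp(-(sv_ll - sv_ss)/beta))``.
    """
    sv_ll, sv_ss, beta = np.asarray(sv_ll, float), np.asarray(sv_ss, float), np.asarray(beta, float)
    if np.any(beta <= 0):
        raise ValueError("beta must be > 0")
    x = (sv_ll - sv_ss) / beta
    # logistic via expit-style branch: never exponentiate a positive argument
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                   np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GroupPrior:
    """Hyperpriors for one group's (log k, log beta) population distribution.

    ``mu_* / tau_*`` parameterize the normal hyperprior on the group mean;
    ``lambda_shape / lambda_rate`` the gamma hyperprior on the group
    precision.  Defaults are weakly informative on the log scale.
    """

    mu_logk_mean: float = -4.0
    mu_logk_sd: float = 2.0
    mu_logbeta_mean: float = 0.0
    mu_logbeta_sd: float = 2.0
    lambda_shape: float = 1.0
    lambda_rate: float = 0.5

    def __post_init__(self):
        if self.mu_logk_sd <= 0 or self.mu_logbeta_sd <= 0:
            raise ValueError("hyperprior SDs must be > 0")
        if self.lambda_shape <= 0 or self.lambda_rate <= 0:
            raise ValueError("gamma hyperparameters must be > 0")


@dataclass
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 3500
    target_accept: float = 0.44  # componentwise random-walk MH sweet spot
    rhat_max: float = 1.05
    ess_min: float = 400.0
    prior: GroupPrior = field(default_factory=GroupPrior)
    on_nonconvergence: str = "raise"  # or "warn"


@dataclass
class HierarchicalFit:
    """Posterior samples and summaries from the hierarchical choice model.

    ``logk`` / ``logbeta`` have shape (chains, draws, n_participants); group
    arrays map group label -> (chains, draws) samples of the group mean and
    precision.  ``summary`` holds one row per participant with posterior
    medians, the log of the median k, and diagnostics.
    """

    participants: list
    groups: list
    logk: np.ndarray
    logbeta: np.ndarray
    group_mu_logk: dict
    group_lambda_logk: dict
    group_mu_logbeta: dict
    group_lambda_logbeta: dict
    summary: pd.DataFrame
    n_trials: dict

    def median_logk(self) -> pd.Series:
        return self.summary.set_index("participant")["log_k"]


def _pad_datasets(datasets: dict) -> tuple[list, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-participant trial tables into masked (P, T) arrays."""
    pids = list(datasets)
    tmax = max(len(d) for d in datasets.values())
    P = len(pids)
    ss_a = np.zeros((P, tmax)); ss_d = np.zeros((P, tmax))
    ll_a = np.ones((P, tmax)); ll_d = np.zeros((P, tmax))
    y = np.zeros((P, tmax)); mask = np.zeros((P, tmax))
    for i, pid in enumerate(pids):
        df = datasets[pid]
        n = len(df)
        ss_a[i, :n] = df["ss_amount"].to_numpy(float)
        ss_d[i, :n] = df["ss_delay"].to_numpy(float)
        ll_a[i, :n] = df["ll_amount"].to_numpy(float)
        ll_d[i, :n] = df["ll_delay"].to_numpy(float)
        y[i, :n] = (df["choice"].to_numpy() == "LL").astype(float)
        mask[i, :n] = 1.0
    return pids, ss_a, ss_d, ll_a, ll_d, y, mask


def _loglik(logk, logbeta, ss_a, ss_d, ll_a, ll_d, y, mask):
    """Bernoulli log-likelihood per participant; logk/logbeta shape (P,)."""
    k = np.exp(logk)[:, None]
    beta = np.exp(logbeta)[:, None]
    sv_ll = ll_a / (1.0 + k * ll_d)
    sv_ss = ss_a / (1.0 + k * ss_d)
    x = (sv_ll - sv_ss) / beta
    # log p_LL = -log(1+exp(-x)); log p_SS = -log(1+exp(x))
    lp_ll = -np.logaddexp(0.0, -x)
    lp_ss = -np.logaddexp(0.0, x)
    return np.sum(mask * (y * lp_ll + (1.0 - y) * lp_ss), axis=1)


def _as_frame(dataset) -> pd.DataFrame:
    if isinstance(dataset, pd.DataFrame):
        return dataset
    return dataset.to_frame()  # ChoiceDataset


def fit_hierarchical(datasets: dict, groups: dict, mcmc: MCMCConfig | None = None,
                     seed: int = 0) -> HierarchicalFit:
    """Fit the two-level discounting model to per-participant choice tables.

    Parameters
    ----------
    datasets
        Mapping participant id -> choice table (``ChoiceDataset`` or tidy
        DataFrame with columns ss_amount, ss_delay, ll_amount, ll_delay,
        choice in {"SS", "LL"}).
    groups
        Mapping participant id -> group label; each label gets its own
        population distribution.
    """
    mcmc = mcmc or MCMCConfig()
    if not datasets:
        raise ValueError("no datasets supplied")
    frames = {pid: _as_frame(d) for pid, d in datasets.items()}
    for pid, df in frames.items():
        if len(df) < 10:
            raise ValueError(f"participant {pid}: need >= 10 choices, got {len(df)}")
        if pid not in groups:
            raise ValueError(f"participant {pid} has no group label")
    if all((df["choice"] == df["choice"].iloc[0]).all() for df in frames.values()):
        warnings.warn("every participant made identical choices on all trials; "
                      "k and beta are weakly identified and posteriors will be wide",
                      UserWarning, stacklevel=2)

    pids, ss_a, ss_d, ll_a, ll_d, y, mask = _pad_datasets(frames)
    P = len(pids)
    glabels = sorted(set(groups[p] for p in pids))
    gidx = {g: np.array([i for i, p in enumerate(pids) if groups[p] == g]) for g in glabels}
    prior = mcmc.prior

    C, W, Dn = mcmc.chains, mcmc.warmup, mcmc.draws
    logk_s = np.empty((C, Dn, P)); logbeta_s = np.empty((C, Dn, P))
    mu_k_s = {g: np.empty((C, Dn)) for g in glabels}
    lam_k_s = {g: np.empty((C, Dn)) for g in glabels}
    mu_b_s = {g: np.empty((C, Dn)) for g in glabels}
    lam_b_s = {g: np.empty((C, Dn)) for g in glabels}

    for c in range(C):
        rng = substream(seed, "hier", c)
        # overdispersed chain starts around the hyperprior means
        logk = prior.mu_logk_mean + rng.normal(0, 1.0, P)
        logbeta = prior.mu_logbeta_mean + rng.normal(0, 0.5, P)
        mu_k = {g: prior.mu_logk_mean + rng.normal(0, 1.0) for g in glabels}
        mu_b = {g: prior.mu_logbeta_mean + rng.normal(0, 0.5) for g in glabels}
        lam_k = {g: 1.0 for g in glabels}
        lam_b = {g: 1.0 for g in glabels}
        step_k = np.full(P, 0.5)
        step_b = np.full(P, 0.5)
        shift_k = {g: 0.2 for g in glabels}
        shift_b = {g: 0.2 for g in glabels}
        ll_cur = _loglik(logk, logbeta, ss_a, ss_d, ll_a, ll_d, y, mask)

        mu_k_vec = np.empty(P); lam_k_vec = np.empty(P)
        mu_b_vec = np.empty(P); lam_b_vec = np.empty(P)
        for it in range(W + Dn):
            for g in glabels:
                mu_k_vec[gidx[g]] = mu_k[g]; lam_k_vec[gidx[g]] = lam_k[g]
                mu_b_vec[gidx[g]] = mu_b[g]; lam_b_vec[gidx[g]] = lam_b[g]
            adapt = math.exp(2.0 / (1.0 + 0.05 * it)) if it < W else 1.0

            # componentwise random-walk MH, vectorized across participants
            prop_k = logk + step_k * rng.standard_normal(P)
            ll_prop = _loglik(prop_k, logbeta, ss_a, ss_d, ll_a, ll_d, y, mask)
            log_alpha = (ll_prop - ll_cur
                         - 0.5 * lam_k_vec * ((prop_k - mu_k_vec) ** 2 - (logk - mu_k_vec) ** 2))
            accept = np.log(rng.random(P)) < log_alpha
            logk = np.where(accept, prop_k, logk)
            ll_cur = np.where(accept, ll_prop, ll_cur)
            if it < W:
                step_k = np.clip(step_k * adapt ** (accept - mcmc.target_accept), 1e-3, 5.0)

            prop_b = logbeta + step_b * rng.standard_normal(P)
            ll_prop = _loglik(logk, prop_b, ss_a, ss_d, ll_a, ll_d, y, mask)
            log_alpha = (ll_prop - ll_cur
                         - 0.5 * lam_b_vec * ((prop_b - mu_b_vec) ** 2 - (logbeta - mu_b_vec) ** 2))
            accept = np.log(rng.random(P)) < log_alpha
            logbeta = np.where(accept, prop_b, logbeta)
            ll_cur = np.where(accept, ll_prop, ll_cur)
            if it < W:
                step_b = np.clip(step_b * adapt ** (accept - mcmc.target_accept), 1e-3, 5.0)

            # group translation move: shift a group's mean together with all
            # of its participants, leaving the participant-level prior terms
            # unchanged -- this decorrelates the group location from the slow
            # participant-level random walks on flat likelihood regions
            for g in glabels:
                idx = gidx[g]
                for which in ("k", "b"):
                    scale = (shift_k if which == "k" else shift_b)[g]
                    delta = scale * rng.standard_normal()
                    if which == "k":
                        prop = logk.copy(); prop[idx] += delta
                        ll_prop = _loglik(prop[idx], logbeta[idx], ss_a[idx], ss_d[idx],
                                          ll_a[idx], ll_d[idx], y[idx], mask[idx])
                        mu_old, mu_new = mu_k[g], mu_k[g] + delta
                        mu0, sd0 = prior.mu_logk_mean, prior.mu_logk_sd
                    else:
                        prop = logbeta.copy(); prop[idx] += delta
                        ll_prop = _loglik(logk[idx], prop[idx], ss_a[idx], ss_d[idx],
                                          ll_a[idx], ll_d[idx], y[idx], mask[idx])
                        mu_old, mu_new = mu_b[g], mu_b[g] + delta
                        mu0, sd0 = prior.mu_logbeta_mean, prior.mu_logbeta_sd
                    log_alpha = (np.sum(ll_prop) - np.sum(ll_cur[idx])
                                 - 0.5 * ((mu_new - mu0) ** 2 - (mu_old - mu0) ** 2) / sd0 ** 2)
                    ok = math.log(rng.random()) < log_alpha
                    if ok:
                        ll_cur[idx] = ll_prop
                        if which == "k":
                            logk = prop; mu_k[g] = mu_new
                        else:
                            logbeta = prop; mu_b[g] = mu_new
                    if it < W:
                        d_ = (shift_k if which == "k" else shift_b)
                        d_[g] = min(max(d_[g] * adapt ** (float(ok) - mcmc.target_accept),
                                        1e-3), 2.0)

            # conjugate group-level updates (normal-gamma)
            for g in glabels:
                for vals, mu, lam, mu0, sd0 in (
                    (logk[gidx[g]], mu_k, lam_k, prior.mu_logk_mean, prior.mu_logk_sd),
                    (logbeta[gidx[g]], mu_b, lam_b, prior.mu_logbeta_mean, prior.mu_logbeta_sd),
                ):
                    n = len(vals)
                    lam[g] = rng.gamma(prior.lambda_shape + 0.5 * n,
                                       1.0 / (prior.lambda_rate + 0.5 * np.sum((vals - mu[g]) ** 2)))
                    prec = 1.0 / sd0 ** 2 + n * lam[g]
                    mean = (mu0 / sd0 ** 2 + lam[g] * np.sum(vals)) / prec
                    mu[g] = mean + rng.standard_normal() / math.sqrt(prec)

            if it >= W:
                d = it - W
                logk_s[c, d] = logk; logbeta_s[c, d] = logbeta
                for g in glabels:
                    mu_k_s[g][c, d] = mu_k[g]; lam_k_s[g][c, d] = lam_k[g]
                    mu_b_s[g][c, d] = mu_b[g]; lam_b_s[g][c, d] = lam_b[g]

    fit = _summarize(pids, groups, glabels, logk_s, logbeta_s,
                     mu_k_s, lam_k_s, mu_b_s, lam_b_s,
                     {pid: len(frames[pid]) for pid in pids})
    _check_convergence(fit, mcmc)
    return fit


def _summarize(pids, groups, glabels, logk_s, logbeta_s,
               mu_k_s, lam_k_s, mu_b_s, lam_b_s, n_trials) -> HierarchicalFit:
    med_logk = np.median(logk_s, axis=(0, 1))
    med_logbeta = np.median(logbeta_s, axis=(0, 1))
    rhat_k = np.array([float(az.rhat(logk_s[:, :, i])) for i in range(len(pids))])
    rhat_b = np.array([float(az.rhat(logbeta_s[:, :, i])) for i in range(len(pids))])
    summary = pd.DataFrame({
        "participant": pids,
        "group": [groups[p] for p in pids],
        "median_k": np.exp(med_logk),
        "log_k": med_logk,
        "median_beta": np.exp(med_logbeta),
        "log_beta": med_logbeta,
        "rhat_logk": rhat_k,
        "rhat_logbeta": rhat_b,
        "n_trials": [n_trials[p] for p in pids],
    })
    return HierarchicalFit(
        participants=pids, groups=[groups[p] for p in pids],
        logk=logk_s, logbeta=logbeta_s,
        group_mu_logk=mu_k_s, group_lambda_logk=lam_k_s,
        group_mu_logbeta=mu_b_s, group_lambda_logbeta=lam_b_s,
        summary=summary, n_trials=n_trials,
    )


def _check_convergence(fit: HierarchicalFit, mcmc: MCMCConfig) -> None:
    worst = float(max(fit.summary["rhat_logk"].max(), fit.summary["rhat_logbeta"].max()))
    group_ess = []
    for samples in (*fit.group_mu_logk.values(), *fit.group_mu_logbeta.values()):
        worst = max(worst, float(az.rhat(samples)))
        group_ess.append(float(az.ess(samples)))
    msgs = []
    if worst > mcmc.rhat_max:
        msgs.append(f"split-R-hat {worst:.3f} exceeds {mcmc.rhat_max}")
    if group_ess and min(group_ess) < mcmc.ess_min:
        msgs.append(f"group-parameter ESS {min(group_ess):.0f} below {mcmc.ess_min:.0f}")
    if msgs:
        msg = "MCMC convergence gate failed: " + "; ".join(msgs)
        if mcmc.on_nonconvergence == "warn":
            warnings.warn(msg, UserWarning, stacklevel=3)
        else:
            raise ConvergenceError(msg)


def combine_and_refit(adaptive: dict, fixed: dict, groups: dict,
                      mcmc: MCMCConfig | None = None, seed: int = 0) -> HierarchicalFit:
    """Concatenate each participant's trials from both tasks and refit.

    Both mappings must cover the same participants; per-task fits remain the
    caller's to keep for cross-task reliability checks.
    """
    if set(adaptive) != set(fixed):
        raise ValueError("adaptive and fixed-item datasets cover different participants")
    combined = {
        pid: pd.concat([_as_frame(adaptive[pid]), _as_frame(fixed[pid])], ignore_index=True)
        for pid in adaptive
    }
    return fit_hierarchical(combined, groups, mcmc=mcmc, seed=seed)


def summarize_log_k(fit: HierarchicalFit) -> pd.DataFrame:
    """Per-participant natural log of the posterior-median discount rate."""
    if fit.logk.size == 0:
        raise ValueError("fit has no posterior samples")
    return fit.summary[["participant", "group", "median_k", "log_k"]].copy()


def fit_mle(dataset, bounds=((-12.0, 2.0), (-4.0, 4.0))) -> tuple[float, float]:
    """Independent per-participant maximum-likelihood (log k, log beta).

    No pooling; used as the un-shrunk reference when checking hierarchical
    shrinkage.
    """
    df = _as_frame(dataset)
    ss_a = df["ss_amount"].to_numpy(float)[None, :]
    ss_d = df["ss_delay"].to_numpy(float)[None, :]
    ll_a = df["ll_amount"].to_numpy(float)[None, :]
    ll_d = df["ll_delay"].to_numpy(float)[None, :]
    y = (df["choice"].to_numpy() == "LL").astype(float)[None, :]
    mask = np.ones_like(y)

    def nll(theta):
        return -_loglik(np.array([theta[0]]), np.array([theta[1]]),
                        ss_a, ss_d, ll_a, ll_d, y, mask)[0]

    best = None
    for x0 in ([-4.0, 0.7], [-2.0, 0.0], [-6.0, 1.5]):
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1])
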