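"""Bayesian rating-model fitting, DIC model selection, and the circle-size
correction.

Each participant's ratings (circle diameters as a fraction of the scale) are
fit, one participant at a time with no pooling, by three observation models
for the noiseless rating ``y_hat``:

* linear:    ``y_hat = a*x + b``
* quadratic: ``y_hat = a*x**2 + b*x + c``
* power:     ``y_hat = a*x**b``

with ``y ~ Normal(y_hat, 1/pi)`` and participant-specific precision ``pi``.
Linear and quadratic fits use an exact conjugate normal-gamma Gibbs sampler;
the power model uses adaptive random-walk Metropolis on (a, b) with a Gibbs
step for ``pi``.  Goodness of fit is compared with the deviance information
criterion, ``DIC = Dbar + pD`` where ``pD = Dbar - D(posterior mean)``
(Spiegelhalter's effective parameter count); smaller DIC is better.

The circle-size correction inverts the participant's circle-production power
law: a time-perception rating ``y`` becomes ``(y/a)**(1/b)`` with the
participant-specific circle parameters, isolating subjective time from
distortion introduced by circle production itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "MODELS",
    "RatingMCMCConfig",
    "RatingModelFit",
    "CorrectedRatings",
    "fit_rating_model",
    "compute_dic",
    "correct_time_ratings",
    "model_selection_table",
]

MODELS = ("linear", "quadratic", "power")
_COMPLEXITY = {"linear": 0, "power": 1, "quadratic": 2}  # tie-break: simpler wins
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class RatingMCMCConfig:
    chains: int = 2
    warmup: int = 500
    draws: int = 800
    target_accept: float = 0.3
    coef_sd: float = 10.0  # Normal(0, coef_sd^2) prior on a, b, c
    pi_shape: float = 1e-3  # Gamma prior on the precision
    pi_rate: float = 1e-3


@dataclass
class RatingModelFit:
    """Posterior for one model on one participant's ratings.

    ``samples`` maps parameter name -> array of shape (chains, draws);
    parameter names are the model coefficients plus ``pi``.
    """

    model: str
    x: np.ndarray
    y: np.ndarray
    samples: dict
    n_obs: int
    participant: str = ""
    dic: float = math.nan
    p_d: float = math.nan

    @property
    def medians(self) -> dict:
        return {k: float(np.median(v)) for k, v in self.samples.items()}

    @property
    def means(self) -> dict:
        return {k: float(np.mean(v)) for k, v in self.samples.items()}


@dataclass
class CorrectedRatings:
    """Time ratings after inversion of the circle-production law.

    Corrected values are subjective-time magnitudes and are not bounded by
    the rating scale, so this is a separate container from RatingSession.
    """

    participant: str
    stimuli: np.ndarray  # delays in days
    diameters: np.ndarray  # corrected magnitudes, > 0
    kind: str = "corrected_time"

    def __len__(self):
        return len(self.stimuli)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant": self.participant,
            "kind": self.kind,
            "stimulus_value": self.stimuli,
            "corrected": self.diameters,
        })


def predict(model: str, params: dict, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    if model == "linear":
        return params["a"] * x + params["b"]
    if model == "quadratic":
        return params["a"] * x ** 2 + params["b"] * x + params["c"]
    if model == "power":
        with np.errstate(over="ignore", invalid="ignore"):
            return params["a"] * np.power(x, params["b"])
    raise ValueError(f"unknown model {model!r}")


def _gaussian_loglik(y: np.ndarray, mu: np.ndarray, pi: float) -> float:
    resid = y - mu
    if not np.all(np.isfinite(mu)):
        return -np.inf
    return 0.5 * len(y) * (math.log(pi) - _LOG_2PI) - 0.5 * pi * float(resid @ resid)


def _extract_xy(trials) -> tuple[np.ndarray, np.ndarray, str]:
    if isinstance(trials, tuple) and len(trials) == 2:
        x, y = np.asarray(trials[0], float), np.asarray(trials[1], float)
        return x, y, ""
    x = np.asarray(trials.stimuli, float)
    y = np.asarray(trials.diameters, float)
    if trials.kind == "circle":  # fit against fraction of the reference circle
        x = x / 100.0
    return x, y, getattr(trials, "participant", "")


def _gibbs_linear(X, y, cfg, rng, n_iter):
    """Exact conjugate normal-gamma Gibbs for a Gaussian linear model.

    The coefficient prior is isotropic, so the conditional covariance
    ``(I/s^2 + pi X'X)^-1`` shares eigenvectors with X'X; one eigendecomposition
    up front replaces a matrix inverse per sweep.
    """
    p = X.shape[1]
    c0 = 1.0 / cfg.coef_sd ** 2
    XtX, Xty = X.T @ X, X.T @ y
    evals, Q = np.linalg.eigh(XtX)
    qty = Q.T @ Xty
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    shape = cfg.pi_shape + 0.5 * len(y)
    out = np.empty((n_iter, p + 1))
    for it in range(n_iter):
        resid = y - X @ beta
        pi = min(rng.gamma(shape, 1.0 / (cfg.pi_rate + 0.5 * float(resid @ resid))), 1e12)
        denom = c0 + pi * evals
        beta = Q @ (pi * qty / denom + rng.standard_normal(p) / np.sqrt(denom))
        out[it, :p] = beta
        out[it, p] = pi
    return out


def _mh_power(x, y, cfg, rng, n_iter, warmup):
    """Random-walk Metropolis on (a, b) with a Gauss-Newton-shaped proposal,
    Gibbs on pi.

    The (a, b) posterior is strongly correlated, so spherical proposals mix
    badly; the proposal covariance follows the inverse Fisher information of
    the power model at the least-squares initialization, rescaled by the
    current precision, with a scalar adaptation factor during warmup.
    """
    # profile-likelihood grid initialization: for each candidate exponent the
    # optimal scale is closed-form, which is robust to near-zero noisy ratings
    # (a log-log fit is not)
    b_grid = np.linspace(0.05, 3.0, 60)
    xb = x[None, :] ** b_grid[:, None]
    a_prof = (xb @ y) / np.sum(xb * xb, axis=1)
    ssr_prof = np.sum((y[None, :] - a_prof[:, None] * xb) ** 2, axis=1)
    i0 = int(np.argmin(ssr_prof))
    a, b = float(a_prof[i0]), float(b_grid[i0])
    resid = y - a * x ** b
    ssr = float(resid @ resid)
    pi = min(len(y) / ssr if ssr > 0 else 1e10, 1e10)
    # Gauss-Newton curvature: columns d(a x^b)/da, d(a x^b)/db
    J = np.column_stack([x ** b, a * x ** b * np.log(x)])
    M = J.T @ J + 1e-10 * np.eye(2)
    L = np.linalg.cholesky(np.linalg.inv(M))
    scale = 1.7  # ~2.4/sqrt(2), the optimal Gaussian RW factor in 2 dimensions
    prior_var = cfg.coef_sd ** 2

    def logpost(a_, b_, pi_):
        if b_ <= 0 or b_ > 50:
            return -np.inf
        ll = _gaussian_loglik(y, predict("power", {"a": a_, "b": b_}, x), pi_)
        return ll - 0.5 * (a_ ** 2 + b_ ** 2) / prior_var

    out = np.empty((n_iter, 3))
    for it in range(n_iter):
        resid = y - a * x ** b
        pi = rng.gamma(cfg.pi_shape + 0.5 * len(y),
                       1.0 / (cfg.pi_rate + 0.5 * float(resid @ resid)))
        pi = min(pi, 1e12)
        lp = logpost(a, b, pi)

        step = (scale / math.sqrt(pi)) * (L @ rng.standard_normal(2))
        lp_prop = logpost(a + step[0], b + step[1], pi)
        accept = math.log(rng.random()) < lp_prop - lp
        if accept:
            a, b = a + step[0], b + step[1]
        if it < warmup:
            scale *= math.exp((float(accept) - cfg.target_accept) / (1.0 + 0.05 * it))
            scale = min(max(scale, 1e-4), 50.0)
        out[it] = (a, b, pi)
    return out


def fit_rating_model(trials, model: str, mcmc: RatingMCMCConfig | None = None,
                     seed: int = 0) -> RatingModelFit:
    """Fit one rating model to one participant's session.

    ``trials`` may be a RatingSession, CorrectedRatings, or an ``(x, y)``
    tuple of arrays.  Circle sessions are fit against the target as a
    fraction of the reference (x = percent/100).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    mcmc = mcmc or RatingMCMCConfig()
    x, y, participant = _extract_xy(trials)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct stimulus values")
    if np.allclose(y, y[0]):
        raise ValueError("ratings are constant across stimuli; curvature is unidentifiable")

    names = {"linear": ["a", "b"], "quadratic": ["a", "b", "c"], "power": ["a", "b"]}[model]
    n_iter = mcmc.warmup + mcmc.draws
    chains = []
    for c in range(mcmc.chains):
        rng = substream(seed, "rating", participant, model, c)
        if model == "power":
            raw = _mh_power(x, y, mcmc, rng, n_iter, mcmc.warmup)
        else:
            X = (np.column_stack([x, np.ones_like(x)]) if model == "linear"
                 else np.column_stack([x ** 2, x, np.ones_like(x)]))
            raw = _gibbs_linear(X, y, mcmc, rng, n_iter)
        chains.append(raw[mcmc.warmup:])
    stacked = np.stack(chains)  # (chains, draws, p+1)
    samples = {name: stacked[:, :, i] for i, name in enumerate(names)}
    samples["pi"] = stacked[:, :, len(names)]

    fit = RatingModelFit(model=model, x=x, y=y, samples=samples,
                         n_obs=len(y), participant=participant)
    fit.dic, fit.p_d = compute_dic(fit)
    return fit


def compute_dic(fit: RatingModelFit) -> tuple[float, float]:
    """Deviance information criterion from the stored posterior samples.

    ``DIC = Dbar + pD`` with ``pD = Dbar - D(theta_bar)``, the deviance
    evaluated at the posterior mean of all parameters (including ``pi``).
    """
    names = [k for k in fit.samples if k != "pi"]
    flat = {k: np.ravel(v) for k, v in fit.samples.items()}
    # deviance for every draw at once: predictions broadcast to (draws, n)
    params = {k: flat[k][:, None] for k in names}
    with np.errstate(over="ignore", invalid="ignore"):
        mu = predict(fit.model, params, fit.x[None, :])
    pi = flat["pi"]
    n = len(fit.y)
    ssr = np.sum((fit.y[None, :] - mu) ** 2, axis=1)
    dev = -2.0 * (0.5 * n * (np.log(pi) - _LOG_2PI) - 0.5 * pi * ssr)
    if not np.all(np.isfinite(dev)):
        raise ValueError("non-finite deviance encountered (degenerate precision samples?)")
    d_bar = float(np.mean(dev))
    mean_params = {k: float(np.mean(v)) for k, v in flat.items()}
    d_hat = -2.0 * _gaussian_loglik(
        fit.y, predict(fit.model, mean_params, fit.x), mean_params["pi"])
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d


def correct_time_ratings(time_session, circle_fit: RatingModelFit) -> CorrectedRatings:
    """Invert the circle-production power law on a time-perception session.

    Uses the posterior-median circle parameters: corrected ``y_hat`` =
    ``(y / a) ** (1 / b)``.  With a = b = 1 (a linear, veridical circle
    producer) the operation is the identity.
    """
    if circle_fit.model != "power":
        raise ValueError("circle fit must be a power-model fit")
    med = circle_fit.medians
    a, b = med["a"], med["b"]
    if a <= 0 or b <= 0:
        raise ValueError(f"circle power-law parameters must be > 0 (got a={a}, b={b})")
    y = np.asarray(time_session.diameters, float)
    if np.any(y < 0):
        raise ValueError("observed ratings must be non-negative")
    corrected = np.power(y / a, 1.0 / b)
    return CorrectedRatings(
        participant=getattr(time_session, "participant", ""),
        stimuli=np.asarray(time_session.stimuli, float),
        diameters=corrected,
    )


def model_selection_table(dic_table: pd.DataFrame) -> pd.DataFrame:
    """Sum per-participant DIC within (analysis, group, model) and mark winners.

    Input: tidy frame with columns participant, group, analysis, model, dic
    (one row per fit).  Every (analysis, group, participant) cell must carry
    all three models.  Ties go to the simpler model with a warning.
    """
    required = {"participant", "group", "analysis", "model", "dic"}
    if not required.issubset(dic_table.columns):
        raise ValueError(f"dic_table must have columns {sorted(required)}")
    counts = dic_table.groupby(["analysis", "group", "participant"])["model"].nunique()
    if (counts != len(MODELS)).any():
        bad = counts[counts != len(MODELS)].index.tolist()
        raise ValueError(f"missing model fits for cells: {bad[:5]}")

    summed = (dic_table.groupby(["analysis", "group", "model"], as_index=False)["dic"]
              .sum().rename(columns={"dic": "summed_dic"}))
    summed["winner"] = False
    for (_, _), idx in summed.groupby(["analysis", "group"]).groups.items():
        block = summed.loc[idx]
        best = block["summed_dic"].min()
        tied = block[np.isclose(block["summed_dic"], best)]
        if len(tied) > 1:
            warnings.warn("DIC tie; selecting the simpler model", UserWarning, stacklevel=2)
        win = tied.loc[tied["model"].map(_COMPLEXITY).idxmin()]
        summed.loc[win.name, "winner"] = True
    order = {m: i for i, m in enumerate(MODELS)}
    return (summed.assign(_o=summed["model"].map(order))
            .sort_values(["analysis", "group", "_o"]).drop(columns="_o")
            .reset_index(drop=True))
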