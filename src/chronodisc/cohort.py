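"""Synthetic cohorts for intertemporal-choice studies of pathological gambling.

Generates simulated participants — a healthy-control (HC) and a pathological-
gambling (PG) group — with questionnaire covariates matching published group
moments, plus the latent behavioral parameters that drive the task simulators:
a hyperbolic discount rate ``k`` and softmax decision noise ``beta`` for
choice, power-law scaling/curvature for subjective time and for circle-size
production, a rating precision ``pi``, and expected autobiographical-memory
(AM) / episodic-future-thinking (EFT) internal-detail scores.

Covariates are drawn from truncated normals whose location is solved so the
*truncated* mean equals the configured group mean (plain truncation at zero
would bias low-mean scores such as HC gambling screens upward).  One global
seed fans out into per-participant substreams, so editing the cohort roster
never perturbs other participants' draws.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from ._rng import substream

__all__ = [
    "Participant",
    "LatentProfile",
    "CovariateSpec",
    "GeneratorConfig",
    "generate_cohort",
    "generate_am_eft_scores",
    "cohort_frame",
    "truth_frame",
]

GROUPS = ("HC", "PG")


@dataclass(frozen=True)
class Participant:
    """One simulated participant: group label and questionnaire covariates."""

    id: str
    group: str  # "HC" or "PG"
    bdi: float  # Beck Depression Inventory
    ftnd: float  # Fagerstrom Test for Nicotine Dependence
    audit: float  # Alcohol Use Disorders Identification Test
    kfg: float  # gambling questionnaire (Kurzfragebogen zum Gluecksspielverhalten)
    sogs: float  # South Oaks Gambling Screen
    school_years: int
    age: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name in ("bdi", "ftnd", "audit", "kfg", "sogs", "age"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class LatentProfile:
    """Latent generative parameters for one participant.

    ``log_k`` is the natural-log hyperbolic discount rate (1/days); ``beta``
    the softmax temperature divisor (EUR; larger = noisier choice); the two
    power laws are subjective time ``a_time * D**b_time`` and circle
    production ``a_circ * m**b_circ``; ``pi`` is the precision (1/variance)
    of the Gaussian rating error; detail scores are expected AM/EFT internal-
    detail sums.
    """

    log_k: float
    beta: float
    a_time: float
    b_time: float
    a_circ: float
    b_circ: float
    pi: float
    eft_details: float
    am_details: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.pi <= 0:
            raise ValueError("pi must be > 0")
        if self.b_time <= 0 or self.b_circ <= 0:
            raise ValueError("power-law exponents must be > 0")
        if self.eft_details < 0 or self.am_details < 0:
            raise ValueError("detail scores must be >= 0")

    @property
    def k(self) -> float:
        return math.exp(self.log_k)


@dataclass(frozen=True)
class CovariateSpec:
    """Per-group mean/SD and truncation bounds for one questionnaire score."""

    hc_mean: float
    hc_sd: float
    pg_mean: float
    pg_sd: float
    lower: float = 0.0
    upper: float = math.inf
    integer: bool = False

    def moments(self, group: str) -> tuple[float, float]:
        return (self.hc_mean, self.hc_sd) if group == "HC" else (self.pg_mean, self.pg_sd)


def _default_covariates() -> dict[str, CovariateSpec]:
    # Group moments follow the published HC/PG sample description; bounds are
    # the questionnaires' score ranges.
    return {
        "bdi": CovariateSpec(4.6, 4.07, 16.5, 9.48, 0.0, 63.0),
        "ftnd": CovariateSpec(3.5, 2.59, 4.45, 2.76, 0.0, 10.0),
        "audit": CovariateSpec(7.15, 7.37, 10.3, 6.28, 0.0, 40.0),
        "kfg": CovariateSpec(1.75, 2.71, 30.15, 7.74, 0.0, 60.0),
        "sogs": CovariateSpec(0.45, 0.60, 9.65, 3.01, 0.0, 20.0),
        "school_years": CovariateSpec(10.0, 1.0, 10.0, 1.0, 9.0, 13.0, integer=True),
        "age": CovariateSpec(32.55, 11.0, 32.9, 11.0, 18.0, 75.0),
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Latent discount rates are normal on the natural-log scale with per-group
    means; ``logk_bdi_slope`` couples log k to the participant's *within-group*
    standardized BDI (negative: more depressed -> shallower discounting) so the
    marginal group means stay at the configured bases.
    """

    covariates: dict[str, CovariateSpec] = field(default_factory=_default_covariates)
    logk_mean_hc: float = -4.5
    logk_mean_pg: float = -3.8
    logk_sd: float = 1.0
    logk_bdi_slope: float = -0.5
    logbeta_mean: float = 0.7  # beta ~ 2 EUR
    logbeta_sd: float = 0.5
    a_time_mean: float = 0.05
    a_time_sd: float = 0.01
    b_time_mean: float = 0.5
    b_time_sd: float = 0.1
    a_circ_mean: float = 1.0
    a_circ_sd: float = 0.05
    b_circ_mean: float = 0.8
    b_circ_sd: float = 0.1
    log_pi_mean: float = math.log(400.0)  # rating SD ~ 0.05 of the scale
    log_pi_sd: float = 0.3
    details_mean: float = 40.0
    details_sd: float = 12.0
    am_eft_rho: float = 0.9

    def validate(self) -> None:
        for name, spec in self.covariates.items():
            if spec.hc_sd < 0 or spec.pg_sd < 0:
                raise ValueError(f"covariate {name!r}: SD must be >= 0")
        for name in ("logk_sd", "logbeta_sd", "a_time_sd", "b_time_sd",
                     "a_circ_sd", "b_circ_sd", "log_pi_sd", "details_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.am_eft_rho <= 1.0:
            raise ValueError("am_eft_rho must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "covariates" in d:
            d["covariates"] = {
                k: (v if isinstance(v, CovariateSpec) else CovariateSpec(**v))
                for k, v in d["covariates"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@functools.lru_cache(maxsize=512)
def _matched_location(mean: float, sd: float, lower: float, upper: float) -> float:
    """Pre-truncation location whose truncated-normal mean equals ``mean``."""

    def trunc_mean(loc: float) -> float:
        a, b = (lower - loc) / sd, (upper - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    try:
        return float(optimize.brentq(lambda m: trunc_mean(m) - mean,
                                     mean - 8 * sd, mean + 8 * sd, xtol=1e-10))
    except ValueError:  # target mean not bracketed (extreme truncation)
        return mean


def _matched_truncnorm(mean: float, sd: float, lower: float, upper: float,
                       rng: np.random.Generator, size=None):
    """Truncated-normal draw whose truncated mean equals ``mean``.

    Solves for the pre-truncation location; the scale stays ``sd``.
    Degenerate SD returns the mean exactly.
    """
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    if not lower < upper:
        raise ValueError("lower bound must be below upper bound")
    mean = float(np.clip(mean, lower + 1e-12, upper - 1e-12 if math.isfinite(upper) else mean))
    loc = _matched_location(mean, sd, lower, upper)
    a, b = (lower - loc) / sd, (upper - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _positive_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal draw truncated just above zero (plain truncation; shift negligible
    at the >4-sigma-from-zero defaults used here)."""
    if sd == 0:
        return mean
    a = (1e-9 - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def generate_am_eft_scores(profile: LatentProfile, rho: float, seed: int,
                           sd_am: float = 12.0, sd_eft: float = 12.0,
                           participant: object = 0) -> tuple[float, float]:
    """Draw one correlated (AM, EFT) internal-detail score pair.

    Scores are bivariate normal around the profile's expected detail scores
    with correlation ``rho`` (shared across a cohort, so the cohort-level
    sample correlation converges to ``rho``), truncated at zero.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = substream(seed, "am_eft", participant)
    z1, z3 = rng.standard_normal(2)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * z3
    am = max(0.0, profile.am_details + sd_am * z1)
    eft = max(0.0, profile.eft_details + sd_eft * z2)
    return am, eft


def generate_cohort(n_hc: int, n_pg: int, config: GeneratorConfig | None = None,
                    seed: int = 0) -> list[tuple[Participant, LatentProfile]]:
    """Generate a reproducible synthetic cohort of HC and PG participants.

    Returns one (Participant, LatentProfile) pair per participant; the latent
    profile is ground truth for recovery tests and is never an input to the
    inference modules.
    """
    if n_hc < 1 or n_pg < 1:
        raise ValueError("need at least one participant per group")
    config = config or GeneratorConfig()
    config.validate()

    cohort: list[tuple[Participant, LatentProfile]] = []
    labels = [("HC", i) for i in range(n_hc)] + [("PG", i) for i in range(n_pg)]
    for group, idx in labels:
        pid = f"{group}{idx + 1:03d}"
        rng = substream(seed, "cohort", pid)

        cov: dict[str, float] = {}
        for name, spec in config.covariates.items():
            mean, sd = spec.moments(group)
            v = float(_matched_truncnorm(mean, sd, spec.lower, spec.upper, rng))
            cov[name] = round(v) if spec.integer else v
        participant = Participant(
            id=pid, group=group,
            bdi=cov["bdi"], ftnd=cov["ftnd"], audit=cov["audit"],
            kfg=cov["kfg"], sogs=cov["sogs"],
            school_years=int(cov["school_years"]), age=cov["age"],
        )

        bdi_mean, bdi_sd = config.covariates["bdi"].moments(group)
        z_bdi = 0.0 if bdi_sd == 0 else (participant.bdi - bdi_mean) / bdi_sd
        base = config.logk_mean_hc if group == "HC" else config.logk_mean_pg
        log_k = base + config.logk_bdi_slope * z_bdi + config.logk_sd * rng.standard_normal()
        beta = math.exp(config.logbeta_mean + config.logbeta_sd * rng.standard_normal())
        profile = LatentProfile(
            log_k=float(log_k),
            beta=float(beta),
            a_time=_positive_normal(config.a_time_mean, config.a_time_sd, rng),
            b_time=_positive_normal(config.b_time_mean, config.b_time_sd, rng),
            a_circ=_positive_normal(config.a_circ_mean, config.a_circ_sd, rng),
            b_circ=_positive_normal(config.b_circ_mean, config.b_circ_sd, rng),
            pi=math.exp(config.log_pi_mean + config.log_pi_sd * rng.standard_normal()),
            eft_details=config.details_mean,
            am_details=config.details_mean,
        )
        cohort.append((participant, profile))
    return cohort


def cohort_frame(cohort: Iterable[tuple[Participant, LatentProfile]]) -> pd.DataFrame:
    """Participant covariate table (one row per participant, no latent truth)."""
    rows = [asdict(p) for p, _ in cohort]
    return pd.DataFrame(rows)


def truth_frame(cohort: Iterable[tuple[Participant, LatentProfile]]) -> pd.DataFrame:
    """Latent-truth table; consumed only by parameter-recovery reports."""
    rows = [{"id": p.id, "group": p.group, **asdict(prof)} for p, prof in cohort]
    return pd.DataFrame(rows)
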