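"""Group-level statistics for the discounting / time-perception analysis.

Covers the scoring and testing layer: AMI internal-detail sum scores, the
compound addiction-severity score, Welch (unequal-variance) group
comparisons with Cohen's d, Pearson correlations and the Fisher-z comparison
of two independent correlations, Cronbach's alpha for inter-rater
reliability, and the multiple regression predicting log k from z-scored
predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AmiRecord",
    "RegressionResult",
    "internal_details_sum",
    "addiction_severity",
    "welch_t",
    "pearson_r",
    "compare_independent_correlations",
    "cronbach_alpha",
    "regress_log_k",
]

INTERNAL_SUBCATEGORIES = ("event", "place", "time", "perceptual", "emotion_thought")


@dataclass(frozen=True)
class AmiRecord:
    """Detail counts for one participant in one condition (AM or EFT).

    ``internal`` is a (5, n_cues) array: one row per internal sub-category
    (event, place, time, perceptual, emotion/thought), one column per
    recorded event cue (at most 5; fewer if recordings are missing).
    Semantic and external detail counts are carried but excluded from the
    internal-details sum score.
    """

    participant: str
    condition: str  # "AM" or "EFT"
    internal: np.ndarray
    semantic: float = 0.0
    external: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.internal, float)
        object.__setattr__(self, "internal", arr)
        if arr.ndim != 2 or arr.shape[0] != len(INTERNAL_SUBCATEGORIES):
            raise ValueError("internal must be a (5, n_cues) array")
        if arr.shape[1] < 1:
            raise ValueError("at least one recorded cue is required")
        if np.any(arr < 0) or self.semantic < 0 or self.external < 0:
            raise ValueError("detail counts must be >= 0")
        if self.condition not in ("AM", "EFT"):
            raise ValueError("condition must be 'AM' or 'EFT'")


@dataclass(frozen=True)
class RegressionResult:
    predictors: list
    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    adj_r2: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predictor": self.predictors, "coef": self.coef, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
        })


def internal_details_sum(record: AmiRecord) -> float:
    """Internal-details sum score: average each sub-category across the
    recorded cues, then sum the five sub-category means.  Semantic and
    external details are excluded."""
    return float(np.sum(np.mean(record.internal, axis=1)))


def addiction_severity(kfg, sogs) -> np.ndarray:
    """Compound addiction-severity score: the mean of the two questionnaires'
    z-scores, standardized over the full sample (both groups pooled)."""
    kfg = np.asarray(kfg, float)
    sogs = np.asarray(sogs, float)
    if kfg.shape != sogs.shape:
        raise ValueError("KFG and SOGS must cover the same participants")
    out = []
    for v in (kfg, sogs):
        sd = np.std(v, ddof=1)
        if sd == 0:
            raise ValueError("zero variance in a questionnaire score")
        out.append((v - np.mean(v)) / sd)
    return (out[0] + out[1]) / 2.0


def welch_t(x, y) -> tuple[float, float, float, float]:
    """Welch's unequal-variance t-test plus pooled-SD Cohen's d.

    Returns (t, Satterthwaite df, two-sided p, d); the sign convention is
    (x - y), so call as welch_t(hc, pg) for HC-minus-PG contrasts.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    res = sps.ttest_ind(x, y, equal_var=False)
    nx, ny = len(x), len(y)
    pooled = math.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
                       / (nx + ny - 2))
    d = (np.mean(x) - np.mean(y)) / pooled if pooled > 0 else 0.0
    return float(res.statistic), float(res.df), float(res.pvalue), float(d)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-based p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def compare_independent_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher-z test for the difference of two independent correlations.

    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def cronbach_alpha(scores) -> float:
    """Cronbach's alpha over a raters x items score matrix.

    ``alpha = k/(k-1) * (1 - sum(var_rater) / var_total)`` where ``k`` is the
    number of raters, ``var_rater`` each rater's variance across items and
    ``var_total`` the variance of per-item total scores.
    """
    m = np.asarray(scores, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a (raters >= 2) x (items >= 2) matrix")
    k = m.shape[0]
    var_raters = np.var(m, axis=1, ddof=1)
    var_total = np.var(np.sum(m, axis=0), ddof=1)
    if var_total == 0:
        raise ValueError("degenerate total-score variance")
    return float(k / (k - 1) * (1.0 - np.sum(var_raters) / var_total))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance predictor")
    return (v - np.mean(v)) / sd


def regress_log_k(log_k, predictors: dict, include_eft: bool = True) -> RegressionResult:
    """OLS of log k on z-scored predictors.

    ``predictors`` maps name -> vector; a ``group`` entry may be labels
    ("HC"/"PG") or 0/1 codes and is z-scored after coding.  ``include_eft``
    toggles the six-predictor variant (with the EFT detail score) versus the
    five-predictor variant.
    """
    y = np.asarray(log_k, float)
    names = [n for n in predictors if include_eft or n != "eft_sum"]
    cols = []
    for name in names:
        v = np.asarray(predictors[name])
        if v.dtype.kind in "OUS":  # group labels
            v = (v == "PG").astype(float)
        cols.append(_zscore(v.astype(float)))
    X = np.column_stack(cols)
    n, p = X.shape
    if n != len(y):
        raise ValueError("predictor/outcome length mismatch")
    if n <= p + 2:
        raise ValueError("too few observations for the number of predictors")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("perfectly collinear predictors")

    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        predictors=names,
        coef=np.asarray(model.params[1:]),
        se=np.asarray(model.bse[1:]),
        ci_low=np.asarray(ci[1:, 0]),
        ci_high=np.asarray(ci[1:, 1]),
        p=np.asarray(model.pvalues[1:]),
        adj_r2=float(model.rsquared_adj),
        n=n,
    )
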