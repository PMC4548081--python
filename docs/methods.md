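# Methods and design notes

## Scope and philosophy

The package reconstructs a complete analysis chain for a two-group
(healthy-control vs. pathological-gambling) study of temporal discounting,
time perception, and episodic future thinking. Because raw behavioral data
of this kind are typically unavailable, the chain is validated by *parameter
recovery*: the synthetic-cohort module generates participants with known
latent parameters, the task module produces trial-level data from them, and
the inference modules must recover what was planted. Every stochastic
component runs off one global seed that fans out into named substreams
(per stage, per participant), so adding or removing a participant never
perturbs anyone else's draws and any run is bit-reproducible.

## Synthetic cohorts

Covariates (BDI, FTND, AUDIT, KFG, SOGS, school years, age) are truncated
normals with group-specific moments taken from a published clinical sample
description (e.g. BDI: HC 4.6 ± 4.07, PG 16.5 ± 9.48) and bounds at the
questionnaires' score ranges. Plain truncation at zero would shift low-mean
scores (HC SOGS 0.45 ± 0.60 by almost one point), so the generator solves
for the pre-truncation location at which the *truncated* mean equals the
configured mean; the configured SD is the pre-truncation scale.

Latent behavioral parameters:

| parameter | default | meaning |
|---|---|---|
| log k | HC −4.5, PG −3.8 (SD 1.0) | natural-log hyperbolic discount rate, 1/days |
| BDI slope on log k | −0.5 per within-group SD | depression attenuates discounting |
| log β | 0.7 ± 0.5 | log softmax temperature (EUR); β≈2 |
| a_time, b_time | 0.05 ± 0.01, 0.5 ± 0.1 | subjective-time power law a·D^b |
| a_circ, b_circ | 1.0 ± 0.05, 0.8 ± 0.1 | circle-production power law |
| log π | log 400 ± 0.3 | rating precision; rating SD ≈ 0.05 of the scale |
| AM/EFT details | 40 ± 12, r = 0.9 | internal-detail sum scores |

The group difference in discounting is deliberately small at the margin:
the direct group effect (+0.7 on log k) is partly offset by the negative
BDI coupling (PG score higher on BDI), so a raw group *t*-test on log k is
weak while the regression that controls for BDI recovers both effects —
the qualitative pattern reported for real PG samples. The BDI coupling is
centered within group, so the marginal group means stay at the configured
bases. Values not available from published tables (the generative effect
sizes, power-law spreads) are conventions chosen once to produce realistic
rating ranges (diameters ~0.05–0.8 over 1–190 days) and are fully
config-overridable; they are not estimates of any real population.

AM and EFT detail scores are correlated Gaussians truncated at zero
(default r = 0.9, matching the high AM–EFT correlations seen empirically);
no narrative content is modeled.

## Task simulators

**Adaptive staircase.** Seven delays (1–180 days), SS fixed at 20 EUR
immediate, LL amount bisected within configurable bounds: start at the
midpoint with a half-range initial step, step halving every trial, moving
down after an LL choice and up after an SS choice, clipped to the bounds.
With this geometry a deterministic agent's final amount is within one final
step (range/2^n_trials) of the closed-form indifference value 20·(1+kD)
whenever that value is bracketed, and saturates exactly at a bound when it
is not (e.g. k = 0 ends at the lower bound). The default is 6 trials per
delay (42 choices); the fixed-item task adds the 27-item monetary-choice
questionnaire for ~70 combined choices.

**Time-perception session.** 18 delays spanning 1–190 days, split into two
presentation sets (odd-indexed delays ascending, even-indexed descending —
the split rule is a convention and configurable). Noiseless production
composes the two power laws, diameter = a_circ·(a_time·D^b_time)^b_circ;
Gaussian noise with precision π is added on the diameter scale and clipped
to (0, 1]. Within a set, once a produced diameter exceeds 90% of the scale,
all *longer* delays of that set are dropped (ceiling rule); the rule can
never remove a delay shorter than the trigger. The 10-s minimum waiting
period and the mid-session break are presentation pacing with no
consequence in this model and are not simulated.

**Circle calibration.** Targets are percentages of a reference circle
(standard references 20/40/60/80% plus, in the pipeline, every diameter the
participant produced in the time session); production is
a_circ·(p/100)^b_circ plus the same Gaussian noise. Whether participants
perceive "size" as diameter or area is immaterial here: the correction
absorbs any monotone power-law distortion.

## Hierarchical discounting inference

Likelihood: Bernoulli per trial with p(LL) from the hyperbola + softmax.
Participant parameters are normal on the log scale (positivity and
identifiability), with group-specific means and precisions:
μ_logk ~ N(−4, 2²), μ_logβ ~ N(0, 2²), λ ~ Gamma(1, 0.5) — weakly
informative and config-exposed.

The sampler is Metropolis-within-Gibbs:

* componentwise adaptive random-walk Metropolis for each participant's
  log k and log β, vectorized across participants (target acceptance 0.44,
  Robbins–Monro scale adaptation frozen after warmup);
* conjugate normal-gamma draws for each group's mean and precision;
* a *group translation move* that proposes shifting a group's mean together
  with all of its members — near-deterministic choosers have plateau
  likelihoods on which individual random walks are slow, and without this
  move the group-level chains inherit that slowness.

Defaults are 4 chains, 1000 warmup, 3500 retained draws (≈10 s for 40
participants × 70 trials on one core). The fit fails loudly (configurable
to a warning) if split-R̂ exceeds 1.05 or group-parameter ESS falls below
400, both computed with arviz. Posterior medians summarize each
participant; log k is the natural log of the median (the distribution of k
is skewed). An independent per-participant maximum-likelihood fit
(L-BFGS-B, multi-start) is provided solely as the un-shrunk reference for
shrinkage checks. A caveat the tests respect: with few trials and
near-deterministic choices the likelihood is piecewise flat and the MLE is
not unique, so shrinkage comparisons are only meaningful in a
graded-noise regime.

## Rating models and DIC

Single-participant fits, never pooled. Priors: coefficients N(0, 10²)
(power-law exponent truncated to (0, 50]), π ~ Gamma(10⁻³, 10⁻³). Linear
and quadratic models use an exact conjugate normal-gamma Gibbs sampler
(one eigendecomposition of X'X replaces per-sweep matrix inversions). The
power model uses random-walk Metropolis on (a, b) with a Gauss–Newton-
shaped proposal covariance — the (a, b) posterior is strongly correlated
and spherical proposals mix badly — plus a Gibbs step for π. The sampler
initializes from a profile-likelihood grid over the exponent (the optimal
scale is closed-form given b), which is robust where a log-log regression
is wrecked by near-zero noisy ratings.

DIC uses Spiegelhalter's effective parameter count: p_D = mean deviance −
deviance at the posterior mean of *all* parameters (including π); DIC =
mean deviance + p_D. Other variants (p_V) exist; this is the canonical
choice for the Gibbs-sampled Gaussian models here. Model selection sums
DIC per (group, analysis, model) and marks the minimum; exact ties break
toward the model with fewer parameters (linear, then power, then
quadratic) with a warning.

The circle-size correction uses the posterior-*median* circle parameters
as a deterministic point transform, ŷ = (y/a)^(1/b); posterior uncertainty
in (a, b) is not propagated, matching the correction's definition as a
data transform. Corrected values are subjective-time magnitudes, not
screen fractions, so they live in a container without the (0, 1] bound and
are refit with all three models before any group comparison of
time-perception parameters.

## Statistics layer

Welch (unequal-variance) t-tests throughout, with Satterthwaite degrees of
freedom from scipy and pooled-SD Cohen's d signed as (first − second), so
HC-vs-PG calls give negative d when PG is larger. Pearson correlations use
the two-sided t-based p; the two-correlation comparison uses the Fisher z
transform with SE sqrt(1/(n₁−3) + 1/(n₂−3)). Cronbach's α is computed
over a raters × items matrix as k/(k−1)·(1 − Σvar_rater/var_total). The
log-k regression z-scores every predictor (group coded 0/1 first) and fits
OLS via statsmodels; the EFT detail score is included by default with a
five-predictor variant behind a flag, since published descriptions of this
regression differ on whether EFT entered.

## Pipeline, sizes, and what the tests show

`run_pipeline` chains generate → simulate → fit-discounting → fit-time →
correct → select-model → stats → recovery, writes tidy CSV artifacts plus
a JSON manifest (config digest, seed, stage wall-times), and only the
recovery report ever reads the latent-truth table. Disabled stages skip
cleanly; downstream stages that need them are skipped too, except the
regression, which simply drops predictors it cannot compute and is skipped
entirely when the cohort is smaller than the predictor count allows.

Desk-scale defaults keep everything on one core: the acceptance script's
full pipeline (40 participants) runs in about a minute; the model-
selection study in the test suite uses 2-chain, 400-draw rating fits for
its 3600 fits. Passing tests demonstrate internal consistency — that the
inference recovers what the generator planted under the stated noise — not
that any particular clinical population behaves this way: the generator
draws independent trials with stationary parameters, and does not model
session effects, lapses, reaction times, or rater behavior beyond additive
noise.

## Known limitations

* Only the hyperbolic discount function is implemented (no exponential or
  quasi-hyperbolic alternatives), and no reaction-time likelihoods.
* The staircase's historical trial counts and adjustment rule are not
  documented in the source literature; the bisection design here is a
  faithful generic staircase, fully configurable.
* DIC is the only model-comparison criterion; WAIC/LOO would require
  pointwise likelihood bookkeeping not kept here.
* Correction by posterior medians ignores circle-parameter uncertainty,
  which inflates apparent rating noise for participants with extreme
  circle exponents.
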