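"""Hyperbolic value / softmax equations and the hierarchical choice model."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chronodisc import (KIRBY_ITEMS, MCMCConfig, choice_probability,
                        combine_and_refit, fit_hierarchical, fit_mle,
                        generate_cohort, run_adaptive_task, run_fixed_item_task,
                        subjective_value, summarize_log_k, StaircaseConfig)
from chronodisc.discounting import _loglik
from chronodisc.stats import pearson_r
from tests.conftest import noiseless_profile


class TestSubjectiveValue:
    @pytest.mark.parametrize("A,k,D,expected", [
        (40.0, 0.0, 180.0, 40.0),
        (40.0, 0.1, 10.0, 20.0),
        (20.0, 0.05, 0.0, 20.0),
    ])
    def test_closed_form(self, A, k, D, expected):
        assert subjective_value(A, k, D) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_delay_and_rate(self):
        D = np.linspace(0, 180, 50)
        sv = subjective_value(40.0, 0.05, D)
        assert np.all(np.diff(sv) < 0)
        k = np.linspace(0.001, 0.3, 50)
        assert np.all(np.diff(subjective_value(40.0, k, 30.0)) < 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            subjective_value(-1.0, 0.1, 10.0)
        with pytest.raises(ValueError):
            subjective_value(40.0, -0.1, 10.0)


class TestChoiceProbability:
    def test_equal_values_give_half(self):
        for beta in (0.01, 1.0, 100.0):
            assert choice_probability(25.0, 25.0, beta) == pytest.approx(0.5)

    def test_deterministic_limit(self):
        assert choice_probability(30.0, 20.0, 1e-12) == pytest.approx(1.0, abs=1e-12)

    def test_unit_logistic_value(self):
        assert choice_probability(21.0, 20.0, 1.0) == pytest.approx(
            0.7310585786300049, abs=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(sv1=st.floats(-1e4, 1e4), sv2=st.floats(-1e4, 1e4),
           beta=st.floats(1e-6, 1e4))
    def test_probabilities_sum_to_one_without_overflow(self, sv1, sv2, beta):
        p = choice_probability(sv1, sv2, beta)
        q = choice_probability(sv2, sv1, beta)
        assert np.isfinite(p) and 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            choice_probability(1.0, 0.0, 0.0)


def test_bernoulli_likelihood_matches_hand_computation():
    """Five-trial toy set: model log-likelihood equals the hand-computed sum
    of Bernoulli log-probabilities from the value/softmax equations."""
    trials = pd.DataFrame({
        "ss_amount": [20.0] * 5, "ss_delay": [0.0] * 5,
        "ll_amount": [30.0, 40.0, 50.0, 25.0, 80.0],
        "ll_delay": [10.0, 30.0, 60.0, 5.0, 180.0],
        "choice": ["LL", "SS", "LL", "SS", "LL"],
    })
    k, beta = 0.03, 2.0
    expected = 0.0
    for row in trials.itertuples():
        p_ll = choice_probability(subjective_value(row.ll_amount, k, row.ll_delay),
                                  subjective_value(row.ss_amount, k, row.ss_delay),
                                  beta)
        expected += math.log(p_ll if row.choice == "LL" else 1.0 - p_ll)
    got = _loglik(np.array([math.log(k)]), np.array([math.log(beta)]),
                  trials.ss_amount.to_numpy()[None, :], trials.ss_delay.to_numpy()[None, :],
                  trials.ll_amount.to_numpy()[None, :], trials.ll_delay.to_numpy()[None, :],
                  (trials.choice == "LL").to_numpy(float)[None, :],
                  np.ones((1, 5)))[0]
    assert got == pytest.approx(expected, abs=1e-10)


def _simulate_cohort_choices(cohort, seed, staircase=None):
    adaptive, fixed, groups = {}, {}, {}
    for p, prof in cohort:
        ds, _ = run_adaptive_task(prof, staircase, seed=seed, participant=p.id)
        adaptive[p.id] = ds
        fixed[p.id] = run_fixed_item_task(prof, seed=seed, participant=p.id)
        groups[p.id] = p.group
    return adaptive, fixed, groups


class TestHierarchicalFit:
    def test_recovery_on_small_cohort(self, fast_hier_mcmc):
        cohort = generate_cohort(6, 6, seed=21)
        adaptive, fixed, groups = _simulate_cohort_choices(cohort, seed=21)
        fit = combine_and_refit(adaptive, fixed, groups, fast_hier_mcmc, seed=21)
        truth = {p.id: prof.log_k for p, prof in cohort}
        s = fit.summary.set_index("participant")
        r, _ = pearson_r([truth[p] for p in s.index], s["log_k"])
        assert r >= 0.8

    def test_identical_data_gives_exchangeable_posteriors(self, fast_hier_mcmc):
        prof = noiseless_profile(log_k=math.log(0.02))
        agent = type(prof)(**{**prof.__dict__, "beta": 2.0})
        ds = run_fixed_item_task(agent, list(KIRBY_ITEMS) * 3, seed=4)
        datasets = {f"P{i}": ds for i in range(6)}
        groups = {f"P{i}": "HC" for i in range(6)}
        fit = fit_hierarchical(datasets, groups, fast_hier_mcmc, seed=5)
        meds = fit.summary["log_k"]
        assert meds.max() - meds.min() < 0.25

    def test_always_ll_concentrates_below_design_bound(self, fast_hier_mcmc):
        """A participant who always takes the delayed option must have k below
        the smallest k at which any item reaches indifference."""
        bound = min((it.ll_amount / it.ss_amount - 1.0) / it.ll_delay
                    for it in KIRBY_ITEMS)
        cohort = generate_cohort(4, 4, seed=9)
        _, fixed, groups = _simulate_cohort_choices(cohort, seed=9)
        patient = noiseless_profile(log_k=-30.0)
        fixed["ALWAYS"] = run_fixed_item_task(patient, list(KIRBY_ITEMS) * 3, seed=9)
        groups["ALWAYS"] = "HC"
        fit = fit_hierarchical(fixed, groups, fast_hier_mcmc, seed=9)
        idx = fit.participants.index("ALWAYS")
        mass = np.mean(np.exp(fit.logk[:, :, idx]) < bound)
        assert mass >= 0.8

    def test_combined_fit_concatenates_trials(self, fast_hier_mcmc):
        cohort = generate_cohort(3, 3, seed=2)
        adaptive, fixed, groups = _simulate_cohort_choices(cohort, seed=2)
        fit = combine_and_refit(adaptive, fixed, groups, fast_hier_mcmc, seed=2)
        for pid in adaptive:
            assert fit.n_trials[pid] == len(adaptive[pid]) + len(fixed[pid])

    def test_disjoint_participants_rejected(self):
        with pytest.raises(ValueError, match="different participants"):
            combine_and_refit({"A": None}, {"B": None}, {})

    def test_identical_choices_warn(self, fast_hier_mcmc):
        prof = noiseless_profile(log_k=-30.0)  # always LL everywhere
        datasets = {f"P{i}": run_fixed_item_task(prof, seed=i, participant=f"P{i}")
                    for i in range(4)}
        groups = {f"P{i}": "HC" for i in range(4)}
        with pytest.warns(UserWarning, match="identical choices"):
            fit_hierarchical(datasets, groups, fast_hier_mcmc, seed=1)

    def test_too_few_trials_rejected(self, fast_hier_mcmc):
        prof = noiseless_profile()
        ds = run_fixed_item_task(prof, list(KIRBY_ITEMS)[:5], seed=0)
        with pytest.raises(ValueError, match=">= 10 choices"):
            fit_hierarchical({"P": ds}, {"P": "HC"}, fast_hier_mcmc)


def test_summarize_log_k_is_log_of_median():
    cohort = generate_cohort(3, 3, seed=13)
    adaptive, fixed, groups = _simulate_cohort_choices(cohort, seed=13)
    mcmc = MCMCConfig(chains=2, warmup=400, draws=400, ess_min=50,
                      on_nonconvergence="warn")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = combine_and_refit(adaptive, fixed, groups, mcmc, seed=13)
    table = summarize_log_k(fit)
    assert np.allclose(table["log_k"], np.log(table["median_k"]))
    ranks_k = table["median_k"].rank()
    assert (ranks_k == table["log_k"].rank()).all()


def test_recovery_improves_with_trial_count(fast_hier_mcmc):
    """Average log-k recovery correlation over seeds is at least as good with
    ~120 trials per participant as with ~30."""
    few = StaircaseConfig(n_trials=4)    # 7 delays x 4 = 28 trials
    many = StaircaseConfig(n_trials=17)  # 7 delays x 17 = 119 trials
    rs = {28: [], 119: []}
    for seed in range(4):
        cohort = generate_cohort(6, 6, seed=100 + seed)
        truth = {p.id: prof.log_k for p, prof in cohort}
        for cfg, n in ((few, 28), (many, 119)):
            adaptive, _, groups = _simulate_cohort_choices(cohort, seed=100 + seed,
                                                           staircase=cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_hierarchical(adaptive, groups, fast_hier_mcmc, seed=seed)
            s = fit.summary.set_index("participant")
            r, _ = pearson_r([truth[p] for p in s.index], s["log_k"])
            rs[n].append(r)
    assert np.mean(rs[119]) >= np.mean(rs[28])


def test_mle_fit_recovers_generating_parameters():
    prof = noiseless_profile(log_k=math.log(0.03))
    agent = type(prof)(**{**prof.__dict__, "beta": 1.0})
    ds = run_fixed_item_task(agent, list(KIRBY_ITEMS) * 10, seed=8)
    logk, logbeta = fit_mle(ds)
    assert logk == pytest.approx(math.log(0.03), abs=0.4)
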