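"""Hierarchical Bayesian discounting fit with parameter recovery.

Simulates both choice tasks for a small cohort, fits the two-level model
(participant log k, log beta drawn from group-specific distributions), and
correlates the posterior-median log k with the generating values.
"""

import chronodisc as cd
from chronodisc.stats import pearson_r

cohort = cd.generate_cohort(8, 8, seed=5)
adaptive, fixed, groups = {}, {}, {}
for participant, profile in cohort:
    ds, _ = cd.run_adaptive_task(profile, seed=5, participant=participant.id)
    adaptive[participant.id] = ds
    fixed[participant.id] = cd.run_fixed_item_task(profile, seed=5,
                                                   participant=participant.id)
    groups[participant.id] = participant.group

fit = cd.combine_and_refit(adaptive, fixed, groups, seed=5)
print(fit.summary[["participant", "group", "median_k", "log_k",
                   "rhat_logk"]].round(3).to_string(index=False))

truth = cd.truth_frame(cohort).set_index("id")
s = fit.summary.set_index("participant")
r, _ = pearson_r(truth.loc[s.index, "log_k"], s["log_k"])
print(f"\nRecovery correlation r(true log k, posterior-median log k) = {r:.3f}")
print("Values near 1 mean the ~70 combined trials per participant identify "
      "individual discount rates well; split-R-hat near 1 confirms the "
      "chains converged.")
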