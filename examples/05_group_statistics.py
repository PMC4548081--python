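"""The group-statistics layer on a synthetic cohort.

Computes AMI internal-detail sum scores, the compound addiction-severity
score, the AM-EFT correlation per group with a Fisher-z comparison, and the
multiple regression of the generating log k on z-scored predictors.
"""

import numpy as np

import chronodisc as cd

cohort = cd.generate_cohort(20, 20, seed=2)
df = cd.cohort_frame(cohort)
truth = cd.truth_frame(cohort)

rec = cd.AmiRecord("demo", "EFT", np.array([[3, 4, 2, 5, 3]] * 5, float))
print(f"internal-details sum score (uniform toy record): "
      f"{cd.internal_details_sum(rec):.1f}")

severity = cd.addiction_severity(df["kfg"], df["sogs"])
print(f"addiction severity (mean z of KFG and SOGS): "
      f"HC {severity[df.group == 'HC'].mean():+.2f}, "
      f"PG {severity[df.group == 'PG'].mean():+.2f}")

scores = {g: np.array([cd.generate_am_eft_scores(prof, 0.9, 2, participant=p.id)
                       for p, prof in cohort if p.group == g])
          for g in ("HC", "PG")}
r_hc, _ = cd.pearson_r(scores["HC"][:, 0], scores["HC"][:, 1])
r_pg, _ = cd.pearson_r(scores["PG"][:, 0], scores["PG"][:, 1])
z, p = cd.compare_independent_correlations(r_hc, 20, r_pg, 20)
print(f"AM-EFT correlation: HC r = {r_hc:.2f}, PG r = {r_pg:.2f}; "
      f"difference z = {z:.2f}, p = {p:.2f}")

res = cd.regress_log_k(truth["log_k"].to_numpy(), {
    "b_exponent": truth["b_time"].to_numpy(),
    "audit": df["audit"].to_numpy(), "ftnd": df["ftnd"].to_numpy(),
    "bdi": df["bdi"].to_numpy(), "group": df["group"].to_numpy(),
    "eft_sum": np.concatenate([scores["HC"][:, 1], scores["PG"][:, 1]]),
})
print("\nregression of log k (z-scored predictors):")
print(res.to_frame().round(3).to_string(index=False))
print(f"adjusted R^2 = {res.adj_r2:.2f}")
print("A positive group coefficient with a negative BDI coefficient means "
      "gambling status steepens discounting while depression attenuates it, "
      "the directional pattern the generator encodes.")
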