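"""Rating-law selection by DIC and the circle-size correction.

Fits linear, quadratic and power models to one participant's simulated time
ratings, corrects the ratings by the participant's own circle-production
power law, and refits to recover the subjective-time exponent.
"""

import math

import chronodisc as cd

profile = cd.LatentProfile(log_k=-4.0, beta=1.5, a_time=0.05, b_time=0.5,
                           a_circ=0.9, b_circ=0.8, pi=1600.0,
                           eft_details=40.0, am_details=40.0)

time_session = cd.simulate_time_session(profile, seed=9)
print("model       DIC  (smaller = better fit)")
for model in cd.MODELS:
    fit = cd.fit_rating_model(time_session, model, seed=9)
    print(f"{model:9s} {fit.dic:7.1f}")

targets = [20.0, 40.0, 60.0, 80.0] + [min(100.0, t.diameter * 100.0)
                                      for t in time_session.trials]
circle_session = cd.simulate_circle_session(profile, targets, seed=9)
circle_fit = cd.fit_rating_model(circle_session, "power", seed=9)
corrected = cd.correct_time_ratings(time_session, circle_fit)
refit = cd.fit_rating_model(corrected, "power", seed=9)

print(f"\ncircle law:  a = {circle_fit.medians['a']:.3f}, "
      f"b = {circle_fit.medians['b']:.3f} (generated: 0.90, 0.80)")
print(f"corrected time exponent b = {refit.medians['b']:.3f} "
      f"(generated b_time = 0.50)")
print("The correction removes circle-production distortion, so the refit "
      "isolates the participant's subjective compression of time; a single "
      "18-trial session leaves visible estimation noise around the "
      "generating exponent.")
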