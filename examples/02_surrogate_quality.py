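"""Fit the Gaussian-process surrogate and check it by cross-validation.

Trains one GP per injury measure on a 200-run campaign and reports
10-fold out-of-fold R^2 — the same validation used to justify replacing
the simulator with the surrogate during optimization.
"""

import restraintopt as ro
from restraintopt.doe import campaign_design, scale_design

cfg = ro.sedan_config()
pairs = scale_design(campaign_design(n=200, seed=0, iterations=6000))
records = ro.generate_dataset(pairs, cfg, seed=1, noisy=False)

report = ro.cross_validate(records, k=10, seed=0)
for name, r2 in report.r2.items():
    print(f"10-fold CV R^2 [{name}]: {r2:.4f}")
print("\nValues near 1 mean the surrogate's out-of-fold predictions almost "
      "coincide with the simulator, so the policy search can run on the "
      "surrogate alone.")

model = ro.fit_gp(records, seed=0)
s = ro.midsize_male_reference()
d = ro.true_optimal_design(s, cfg)
y50 = ro.predict_ucb(model, s, d, level=0.5)
y95 = ro.predict_ucb(model, s, d, level=0.95)
print(f"\nmidsize male at its optimal design, posterior mean: {y50}")
print(f"same point, 95% upper confidence bound:          {y95}")
print("The UCB adds a margin of predictive uncertainty, so designs are "
      "judged by a conservative estimate of their injury measures.")
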