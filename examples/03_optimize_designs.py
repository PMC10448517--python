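"""Optimize the three restraint solutions and compare population risks.

Runs the full two-step method at reduced scale: a noisy simulation
campaign, a GP surrogate served at the 95% UCB, then optimization of
(i) the constant design for the midsize male, (ii) the constant design
for the whole population, and (iii) the adaptive polynomial policy.
"""

import restraintopt as ro
from restraintopt.doe import campaign_design, scale_design
from restraintopt.evaluate import population_risk_table, reduction_summary
from restraintopt.policy_opt import (ObjectiveSpec, SurrogateUCBPredictor,
                                     default_mc_sample, optimize_all)

cfg = ro.sedan_config()
pairs = scale_design(campaign_design(n=200, seed=0, iterations=6000))
records = ro.generate_dataset(pairs, cfg, seed=1)         # 2% observation noise
model = ro.fit_gp(records, seed=0)
pred = SurrogateUCBPredictor(model, level=0.95)

spec = ObjectiveSpec(default_mc_sample(n=128, seed=2), pred)
sols = optimize_all(spec, m=2, seed=0, steps=600, restarts=2,
                    constant_steps=500)

eval_sample = default_mc_sample(n=1024, seed=3)
table = population_risk_table(sols, eval_sample, pred)
print(table.round(4).to_string())
print()
print(reduction_summary(table).round(2).to_string())
print("\nRows: population-mean injury risks per body region and jointly "
      "(Pjoint), plus Pjoint for the midsize male.\nThe adaptive policy "
      "lowers the population Pjoint below both constant designs because it "
      "tailors belt force,\nairbag mass flow and the other settings to each "
      "occupant's anthropometry.")

sols["policy_iii"].to_json("adaptive_policy.json")
print("\nwritten: adaptive_policy.json")
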