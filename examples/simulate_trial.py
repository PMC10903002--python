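"""Simulate one two-arm trial with a 20% proportional slowing.

Builds the packaged placebo trajectory for an amyloid-positive MCI
cohort, draws 300 subjects per arm over a 36-month schedule, and writes
the long-format dataset to CSV.
"""

from progdelay import TreatmentEffectSpec, default_trajectory, generate_trial

traj = default_trajectory()
print("visit months:       ", traj.visit_months)
print("placebo mean CDR-SB:", traj.placebo_means)

eff = TreatmentEffectSpec(slowing_fraction=0.20)
data = generate_trial(traj, eff, n_per_arm=300, duration_months=36, seed=1)
data.to_csv("simulated_trial.csv")

by_arm = data.data.groupby(["arm", "visit_month"])["cdr_sb"].mean().unstack()
print("\nobserved arm means by visit (points):")
print(by_arm.round(2))
print(
    "\nThe active arm tracks the placebo curve evaluated at 80% of elapsed"
    "\ntime, so its mean at 36 months matches placebo at about 29 months."
)
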