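"""Small replication study: median effects and empirical power.

Runs a reduced scenario grid (two sample sizes, two durations, 100
replicates) with a true 20% proportional slowing and prints the median
effect table and the power table. The full grid of the packaged default
(`ScenarioGrid()`) covers 200-700 per arm and 18/24/36 months.
"""

from progdelay import ScenarioGrid, TreatmentEffectSpec, default_trajectory, render_tables, run_study

grid = ScenarioGrid(
    n_per_arm=(300, 700), durations=(18.0, 36.0), n_replicates=100, master_seed=0
)
res = run_study(grid, default_trajectory(), TreatmentEffectSpec(0.20))

tabs = render_tables(res)
print("Median treatment effect at the final visit:")
print(tabs["medians_text"])
print("\nEmpirical power (two-sided Wald, alpha = 0.05):")
print(tabs["power_text"])
print(
    "\nThe time-based model recovers the 20% slowing on the time axis; the"
    "\nscore-scale model reports a larger percent because the trajectory is"
    "\nconvex; the dichotomized Cox analysis discards granularity and has"
    "\nthe least power."
)
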