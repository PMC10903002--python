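"""Fit the three competing analyses to one simulated trial.

Generates a 700-per-arm, 36-month trial with a true 20% proportional
slowing, then fits the time-based progression model (effect in months of
delay), the constrained longitudinal model (effect in CDR-SB points),
and the Cox model on progression to dementia (CDR-SB >= 4.5).
"""

import numpy as np

from progdelay import (
    TreatmentEffectSpec,
    default_trajectory,
    delay_confidence_interval,
    dichotomize_progression,
    fit_cox,
    fit_mmrm,
    fit_pmrm,
    generate_trial,
)

data = generate_trial(
    default_trajectory(), TreatmentEffectSpec(0.20), n_per_arm=700, duration_months=36, seed=11
)

pmrm = fit_pmrm(data)
lo, hi = delay_confidence_interval(pmrm, 36.0)
print("PMRM (time scale):")
print("  delay at 36 months: %.1f months (95%% CI %.1f to %.1f)" % (pmrm.delays[-1], lo, hi))
print("  percent slowing by visit:", np.round(100 * pmrm.percent_slowing, 1))
print("  Wald p at final visit: %.2g" % pmrm.wald_p_final)

mmrm = fit_mmrm(data)
print("\nMMRM (score scale):")
print("  CDR-SB difference at 36 months: %.2f points (SE %.2f)" % (mmrm.cfb_diff_final, mmrm.se))
print("  percent reduction in change from baseline: %.0f%%" % (100 * mmrm.percent_reduction))

cox = fit_cox(dichotomize_progression(data))
print("\nCox (hazard of progressing to dementia):")
print("  HR %.2f, p = %.2g, events: %s" % (cox.hazard_ratio, cox.wald_p, cox.n_events))

print(
    "\nAll three see the same simulated truth (a 20% slowing, ~7.2 months at"
    "\n36 months); they express it in months, points, and a hazard ratio."
)
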