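"""Within-day improvement and overnight setbacks.

The trial-of-day dummies measure how much faster a mouse escapes on later
trials of the same day; the inter-day setback is the rise in predicted
latency from the last trial of one day to the first trial of the next - a
memory-consolidation readout.  Here the generating truth gives trials 2-4 a
6-second advantage over trial 1, so the curve jumps back up overnight.
"""

import numpy as np

from mazelearn import (
    GroupCurve,
    SamplerConfig,
    TrueParameters,
    fit_cohort,
    interday_setbacks,
    simulate_cohort,
    within_day_improvement,
)

GROUP = ("hAPPlow", "sh1")
truth = TrueParameters(
    groups=(GROUP,),
    curves=(GroupCurve(48.0, 0.8, trial_offsets=(-6.0, -6.0, -6.0)),),
    mice_per_group=(14,),
    seed=21,
)
cohort, _ = simulate_cohort(truth)
result = fit_cohort(
    cohort,
    config=SamplerConfig(n_chains=3, burn_in=400, draws_per_chain=600, base_seed=21),
    with_contrasts=False,
)

for day in (2, 5):
    d = within_day_improvement(result.samples, GROUP, day=day, spec=result.spec,
                               n_days=6)
    lo, hi = np.percentile(d, [2.5, 97.5])
    print(f"day {day}: trial-4 minus trial-1 latency {d.mean():+.2f} s "
          f"(95% CI {lo:+.2f}..{hi:+.2f}; truth -6.0, negative = improvement)")

s_all = interday_setbacks(result.samples, GROUP, result.basis, result.spec, n_days=6)
s_last3 = interday_setbacks(result.samples, GROUP, result.basis, result.spec,
                            n_days=6, day_range=(4, 6))
# truth: overnight the 6 s trial-advantage resets and the curve descends
# 0.8 s/trial, so the expected jump is +6 - 0.8 = +5.2 s
for label, s in (("all transitions", s_all), ("last 3 days", s_last3)):
    lo, hi = np.percentile(s, [2.5, 97.5])
    print(f"overnight setback, {label}: {s.mean():+.2f} s "
          f"(95% CI {lo:+.2f}..{hi:+.2f}; positive = regression overnight)")
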