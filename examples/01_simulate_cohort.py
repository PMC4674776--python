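"""Simulate a study-scale synthetic water-maze cohort and inspect it.

The `fig4b-like` scenario generates four genotype-by-treatment groups
(18-28 mice each, 6 hidden-platform training days x 4 trials/day) whose true
per-trial improvements are the published group rates, with right-censoring
of escape latencies at 60 s.
"""

from pathlib import Path

import numpy as np

from mazelearn import scenario, simulate_cohort, write_trials

truth = scenario("fig4b-like")
cohort, _ = simulate_cohort(truth)

print(f"groups             : {cohort.groups}")
print(f"mice per group     : {truth.mice_per_group}")
print(f"records            : {len(cohort.records)} "
      f"({cohort.n_days} days x {cohort.trials_per_day} trials)")
frac = np.mean([r.censored for r in cohort.records])
print(f"censored trials    : {frac:.1%} (timed out at {cohort.censor_limit:.0f} s)")

# censoring concentrates early in training, before the mice have learned
for day in cohort.days:
    day_frac = np.mean([r.censored for r in cohort.records if r.day == day])
    print(f"  day {day}: {day_frac:5.1%} censored")

out = Path("scratch")
out.mkdir(exist_ok=True)
write_trials(cohort, out / "cohort.csv")
truth.to_yaml(out / "truth.yaml")
print(f"wrote {out / 'cohort.csv'} and {out / 'truth.yaml'}")
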