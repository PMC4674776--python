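"""Synthetic water-maze cohorts with known ground truth.

The generator mirrors the analysis model exactly: each group has a latent
mean latency that improves by a constant number of seconds per trial
(optionally plus trial-of-day offsets and linear-in-day drifts), each mouse
adds a Gaussian random intercept and three random spline-coefficient
deviations, Gaussian residual noise is added per trial, and the recorded
latency is the latent value right-censored at the cutoff.  The latent law is
Gaussian, so simulated latencies can fall below zero late in training when
the mean approaches the floor of the scale; these are kept as-is so that the
simulator and the likelihood share one law (empirical CSV loading enforces
positivity separately).

Default noise scales (residual s.d. 10 s, intercept s.d. 5 s, spline s.d.s
2 s) are package choices producing realistic early-training censoring; they
are not study-reported values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .spline import build_basis
from .trial_data import CohortData, TrialRecord


@dataclass
class GroupCurve:
    """Parametric group mean: start latency and constant per-trial improvement.

    mean(day, trial) = start - rate * [(day-1) * trials_per_day + (trial-1)]
                       + offsets[trial] + drifts[trial] * day

    ``offsets``/``drifts`` apply to trials 2..T (length T-1); defaults zero.
    """

    start_latency: float = 45.0
    per_trial_improvement: float = 1.0
    trial_offsets: tuple[float, ...] = (0.0, 0.0, 0.0)
    trial_drifts: tuple[float, ...] = (0.0, 0.0, 0.0)

    def mean(self, day: int, trial: int, trials_per_day: int) -> float:
        k = (day - 1) * trials_per_day + (trial - 1)
        mu = self.start_latency - self.per_trial_improvement * k
        if trial >= 2:
            mu += self.trial_offsets[trial - 2] + self.trial_drifts[trial - 2] * day
        return mu


@dataclass
class TrueParameters:
    """Generating truth for a synthetic cohort: curves, noise scales, shape."""

    groups: tuple[tuple[str, str], ...] = (("WT", "scr"),)
    curves: tuple[GroupCurve, ...] = (GroupCurve(),)
    mice_per_group: tuple[int, ...] = (20,)
    n_days: int = 6
    trials_per_day: int = 4
    censor_limit: float = 60.0
    sd_intercept: float = 5.0
    sd_splines: tuple[float, float, float] = (2.0, 2.0, 2.0)
    sd_residual: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.groups) == len(self.curves) == len(self.mice_per_group)):
            raise ValueError("groups, curves and mice_per_group must align")
        if min(self.mice_per_group) < 1 or self.n_days < 1 or self.trials_per_day < 1:
            raise ValueError("shape counts must be >= 1")
        if self.sd_intercept < 0 or self.sd_residual < 0 or min(self.sd_splines) < 0:
            raise ValueError("standard deviations must be >= 0")
        for c in self.curves:
            if not 0 < c.start_latency <= self.censor_limit:
                raise ValueError(
                    f"start latency must be in (0, {self.censor_limit}], "
                    f"got {c.start_latency}"
                )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrueParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["groups"] = tuple(tuple(g) for g in data["groups"])
        data["curves"] = tuple(
            GroupCurve(
                start_latency=c["start_latency"],
                per_trial_improvement=c["per_trial_improvement"],
                trial_offsets=tuple(c["trial_offsets"]),
                trial_drifts=tuple(c["trial_drifts"]),
            )
            for c in data["curves"]
        )
        data["mice_per_group"] = tuple(data["mice_per_group"])
        data["sd_splines"] = tuple(data["sd_splines"])
        return cls(**data)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def simulate_cohort(truth: TrueParameters) -> tuple[CohortData, TrueParameters]:
    """Generate one cohort under the model, reproducibly from ``truth.seed``.

    Per mouse: random intercept ~ N(0, sd_intercept^2) and three spline
    coefficients ~ N(0, sd_spline_j^2) on the same normalized natural-spline
    basis the analysis uses; per trial: latent = group mean + mouse curve +
    N(0, sd_residual^2), recorded as min(latent, censor_limit) with the
    censored flag.
    """
    rng = np.random.default_rng(truth.seed)
    df = len(truth.sd_splines)
    basis = build_basis(np.arange(1, truth.n_days + 1), df=df)
    bmat = basis.evaluate(np.arange(1, truth.n_days + 1, dtype=float))  # (n_days, df)

    records: list[TrialRecord] = []
    for g, ((geno, treat), curve, n_mice) in enumerate(
        zip(truth.groups, truth.curves, truth.mice_per_group)
    ):
        for m in range(n_mice):
            mouse_id = f"{geno}-{treat}-m{m + 1:02d}"
            u = rng.normal(0.0, truth.sd_intercept)
            v = rng.normal(0.0, truth.sd_splines, size=df)
            for day in range(1, truth.n_days + 1):
                mouse_dev = u + float(bmat[day - 1] @ v)
                for trial in range(1, truth.trials_per_day + 1):
                    latent = (
                        curve.mean(day, trial, truth.trials_per_day)
                        + mouse_dev
                        + rng.normal(0.0, truth.sd_residual)
                    )
                    censored = latent >= truth.censor_limit
                    records.append(
                        TrialRecord(
                            mouse_id=mouse_id,
                            genotype=geno,
                            treatment=treat,
                            day=day,
                            trial=trial,
                            latency=float(truth.censor_limit if censored else latent),
                            censored=bool(censored),
                        )
                    )
    cohort = CohortData(
        records=records,
        groups=list(truth.groups),
        n_days=truth.n_days,
        trials_per_day=truth.trials_per_day,
        censor_limit=truth.censor_limit,
    )
    return cohort, truth


#: Per-trial improvement rates (s per trial) used as group truths in the
#: "fig4b-like" scenario, on the published scale for the four
#: genotype-by-treatment groups.
FIG4B_RATES = {
    ("WT", "scr"): 1.6,
    ("WT", "sh1"): 0.9,
    ("hAPPlow", "scr"): 1.6,
    ("hAPPlow", "sh1"): 0.4,
}

_FIG4B_SIZES = {
    ("WT", "scr"): 26,
    ("WT", "sh1"): 28,
    ("hAPPlow", "scr"): 18,
    ("hAPPlow", "sh1"): 24,
}


def scenario(name: str) -> TrueParameters:
    """Return a packaged, documented scenario by name.

    - ``fig4b-like``: four genotype-by-treatment groups at study scale
      (18-28 mice/group, 6 days x 4 trials, censoring at 60 s) whose true
      per-trial improvements are the four published group rates; start
      latency 45 s.
    - ``null``: four groups sharing one identical curve (for calibration of
      contrast P values).
    - ``tiny``: a 2-mouse fixture for oracle-scale math only; the sampler's
      propriety guard rejects it.
    """
    if name == "fig4b-like":
        groups = tuple(FIG4B_RATES)
        return TrueParameters(
            groups=groups,
            curves=tuple(
                GroupCurve(start_latency=45.0, per_trial_improvement=FIG4B_RATES[g])
                for g in groups
            ),
            mice_per_group=tuple(_FIG4B_SIZES[g] for g in groups),
            seed=7,
        )
    if name == "null":
        groups = tuple(FIG4B_RATES)
        return TrueParameters(
            groups=groups,
            curves=tuple(
                GroupCurve(start_latency=45.0, per_trial_improvement=1.0)
                for _ in groups
            ),
            mice_per_group=(12, 12, 12, 12),
            seed=0,
        )
    if name == "tiny":
        return TrueParameters(
            groups=(("WT", "scr"),),
            curves=(GroupCurve(start_latency=45.0, per_trial_improvement=1.0),),
            mice_per_group=(2,),
            n_days=4,
            trials_per_day=2,
            seed=0,
        )
    raise KeyError(
        f"unknown scenario {name!r}; available: ['fig4b-like', 'null', 'tiny']"
    )


def with_seed(truth: TrueParameters, seed: int) -> TrueParameters:
    return replace(truth, seed=int(seed))


def true_fixed_effects(truth: TrueParameters, basis, spec) -> np.ndarray:
    """Project the generating group curves onto the model's fixed-effect space.

    The parametric curves (linear in cumulative trial plus dummy offsets and
    drifts) lie exactly in the span of {intercept, spline, dummies,
    dummy-by-day}, so the least-squares projection of the noiseless cell
    means is exact (residual ~ 0) and serves as the truth for recovery and
    coverage checks.
    """
    from .design import fixed_row, n_fixed

    p = n_fixed(spec)
    rows = []
    targets = []
    for g, curve in enumerate(truth.curves):
        for day in range(1, truth.n_days + 1):
            for trial in range(1, truth.trials_per_day + 1):
                rows.append(fixed_row(float(day), trial, g, basis, spec))
                targets.append(curve.mean(day, trial, truth.trials_per_day))
    A = np.asarray(rows)
    t = np.asarray(targets)
    beta, res, rank, _ = np.linalg.lstsq(A, t, rcond=None)
    if rank < p:
        raise ValueError("truth projection is rank-deficient; check the model spec")
    return beta
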