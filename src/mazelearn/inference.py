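"""Posterior inference on learning curves.

Turns retained draws into the quantities of scientific interest: population
learning curves (fixed effects only, random effects at zero) with 95%
credible bands on the full day-by-trial grid, per-trial learning rates,
within-day improvement, inter-day setbacks, and contrasts with
credible-interval-inversion P values (twice the smaller posterior tail
probability of the difference relative to zero, so P < 0.05 exactly when the
95% equal-tailed interval excludes zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ModelSpec, fixed_row, n_fixed
from .gibbs import PosteriorSamples
from .spline import SplineBasis


def _group_index(spec: ModelSpec, group: tuple[str, str]) -> int:
    groups = list(spec.groups or ())
    if tuple(group) not in groups:
        raise KeyError(f"unknown group {tuple(group)}; available: {groups}")
    return groups.index(tuple(group))


def _beta_draws(samples: PosteriorSamples, spec: ModelSpec) -> np.ndarray:
    return samples.thinned()[:, : n_fixed(spec)]


def fitted_curve_draws(
    samples: PosteriorSamples,
    group: tuple[str, str],
    basis: SplineBasis,
    spec: ModelSpec,
    n_days: int | None = None,
    day_center: float = 0.0,
) -> np.ndarray:
    """Per-draw population fitted latency over the (day, trial) grid.

    Returns shape (n_draws, n_days, trials_per_day); random effects are at
    zero, so this is the group-level curve shown as posterior mean lines and
    credible bands.
    """
    g = _group_index(spec, group)
    if n_days is None:
        n_days = int(round(basis.boundary_knots[1] - basis.boundary_knots[0])) + 1
    days = np.arange(1, n_days + 1)
    cells = np.stack(
        [
            np.stack(
                [fixed_row(float(d), t, g, basis, spec, day_center)
                 for t in range(1, spec.trials_per_day + 1)]
            )
            for d in days
        ]
    )  # (n_days, trials_per_day, p)
    beta = _beta_draws(samples, spec)
    return np.einsum("dtp,np->ndt", cells, beta)


@dataclass
class LearningCurveSummary:
    """Per-group posterior mean curve with 2.5-97.5 percentile band."""

    group: tuple[str, str]
    table: pd.DataFrame  # day, trial, mean, lo2.5, hi97.5

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df.insert(0, "treatment", self.group[1])
        df.insert(0, "genotype", self.group[0])
        df.to_csv(path, index=False)


def summarize_curve(
    curve_draws: np.ndarray, group: tuple[str, str] = ("", "")
) -> LearningCurveSummary:
    """Summarize per-draw grid curves into mean and 95% credible band."""
    if curve_draws.shape[0] < 100:
        raise ValueError("need >= 100 draws to summarize a curve")
    mean = curve_draws.mean(axis=0)
    lo, hi = np.percentile(curve_draws, [2.5, 97.5], axis=0)
    n_days, tpd = mean.shape
    days, trials = np.meshgrid(np.arange(1, n_days + 1), np.arange(1, tpd + 1),
                               indexing="ij")
    table = pd.DataFrame(
        {
            "day": days.ravel(),
            "trial": trials.ravel(),
            "mean": mean.ravel(),
            "lo2.5": lo.ravel(),
            "hi97.5": hi.ravel(),
        }
    )
    return LearningCurveSummary(group=tuple(group), table=table)


def learning_rate(
    samples: PosteriorSamples,
    group: tuple[str, str],
    basis: SplineBasis,
    spec: ModelSpec,
    n_days: int | None = None,
    method: str = "regression",
) -> np.ndarray:
    """Posterior draws of the per-trial learning rate (seconds per trial).

    ``method="regression"`` (default): the least-squares slope of the
    population fitted latency against the cumulative trial index over the
    whole day-by-trial grid, sign-flipped so positive means improvement.
    This is the average per-trial descent of the curve; for a curve that is
    linear in cumulative trial it equals the endpoint difference divided by
    (total trials - 1), but it uses every grid cell and is therefore a much
    less noisy summary of the same quantity.

    ``method="endpoint"``: first-cell minus last-cell fitted latency divided
    by (total trials - 1).
    """
    curves = fitted_curve_draws(samples, group, basis, spec, n_days=n_days)
    flat = curves.reshape(curves.shape[0], -1)  # cumulative-trial order
    total = flat.shape[1]
    if method == "endpoint":
        return (flat[:, 0] - flat[:, -1]) / (total - 1)
    if method != "regression":
        raise ValueError(f"unknown learning-rate method {method!r}")
    k = np.arange(total, dtype=float)
    w = k - k.mean()
    w /= (w**2).sum()
    return -(flat @ w)


def within_day_improvement(
    samples: PosteriorSamples,
    group: tuple[str, str],
    day: int,
    spec: ModelSpec,
    n_days: int | None = None,
) -> np.ndarray:
    """Posterior draws of (last-trial minus first-trial) fitted latency at a day.

    Equals the last trial's dummy effect plus its linear drift evaluated at
    that day; negative values mean within-day improvement.
    """
    if n_days is not None and not 1 <= day <= n_days:
        raise ValueError(f"day {day} outside training range 1..{n_days}")
    if day < 1:
        raise ValueError(f"day {day} outside training range")
    g = _group_index(spec, group)
    beta = _beta_draws(samples, spec)
    labels = samples.labels
    t_last = spec.trials_per_day
    if spec.group_specific_dummies:
        geno, treat = (spec.groups or ())[g]
        a = beta[:, labels.index(f"{geno}:{treat}:trial{t_last}")]
        b = beta[:, labels.index(f"{geno}:{treat}:trial{t_last}_x_day")]
    else:
        a = beta[:, labels.index(f"shared:trial{t_last}")]
        b = beta[:, labels.index(f"shared:trial{t_last}_x_day")]
    return a + b * float(day)


def interday_setbacks(
    samples: PosteriorSamples,
    group: tuple[str, str],
    basis: SplineBasis,
    spec: ModelSpec,
    day_range: tuple[int, int] | None = None,
    n_days: int | None = None,
) -> np.ndarray:
    """Posterior draws of the mean overnight setback (seconds).

    For each consecutive-day transition d -> d+1 inside ``day_range``, the
    setback is fitted(day d+1, trial 1) - fitted(day d, last trial); draws
    are averaged over the transitions.  Positive values mean performance
    regressed overnight.  ``day_range=(D-2, D)`` restricts to the last three
    training days (two transitions).
    """
    curves = fitted_curve_draws(samples, group, basis, spec, n_days=n_days)
    nd = curves.shape[1]
    if day_range is None:
        day_range = (1, nd)
    lo, hi = int(day_range[0]), int(day_range[1])
    if not (1 <= lo < hi <= nd):
        raise ValueError(
            f"invalid day range {day_range}: need 1 <= start < end <= {nd}"
        )
    jumps = [curves[:, d, 0] - curves[:, d - 1, -1] for d in range(lo, hi)]
    return np.mean(jumps, axis=0)


@dataclass
class ContrastResult:
    """A posterior contrast with credible-interval-inversion P value."""

    label: str
    mean: float
    lo: float
    hi: float
    p_value: float
    p_is_floor: bool
    n_draws: int

    @property
    def p_text(self) -> str:
        return f"< {self.p_value:.2g}" if self.p_is_floor else f"{self.p_value:.2g}"


def contrast(a: np.ndarray, b: np.ndarray, label: str = "") -> ContrastResult:
    """Summarize the draw-matched difference a - b.

    P = 2 * min(fraction of difference draws > 0, fraction < 0); when one
    tail is empty the P value is reported as a floor "< 2/N".  The credible
    interval uses symmetric order statistics (the ceil(0.025 n)-th draw from
    each end), so that for continuous draws "the 95% interval excludes zero"
    and "P < 0.05" agree exactly, including at the boundary.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"draw vectors must be matched 1-D arrays, got {a.shape} vs {b.shape}")
    diff = a - b
    n = len(diff)
    frac_pos = float((diff > 0).mean())
    frac_neg = float((diff < 0).mean())
    p = 2.0 * min(frac_pos, frac_neg)
    floor = p == 0.0
    if floor:
        p = 2.0 / n
    s = np.sort(diff)
    m = max(int(np.ceil(0.025 * n)), 1)
    lo, hi = s[m - 1], s[n - m]
    return ContrastResult(
        label=label,
        mean=float(diff.mean()),
        lo=float(lo),
        hi=float(hi),
        p_value=float(min(p, 1.0)),
        p_is_floor=floor,
        n_draws=n,
    )


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [r.label for r in results],
            "mean": [r.mean for r in results],
            "lo2.5": [r.lo for r in results],
            "hi97.5": [r.hi for r in results],
            "p_value": [r.p_value for r in results],
            "p_is_floor": [r.p_is_floor for r in results],
            "n_draws": [r.n_draws for r in results],
        }
    )


def curves_to_frame(summaries: list[LearningCurveSummary]) -> pd.DataFrame:
    parts = []
    for s in summaries:
        df = s.table.copy()
        df.insert(0, "treatment", s.group[1])
        df.insert(0, "genotype", s.group[0])
        parts.append(df)
    return pd.concat(parts, ignore_index=True)
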