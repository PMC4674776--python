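"""Fixed- and random-effect design assembly for the hierarchical latency model.

The mean model for a record from mouse ``i`` in group ``g`` on day ``d``,
trial ``t`` is

    mu = intercept_g + sum_j beta_gj B_j(d)                  (group spline curve)
        + a_{t,g} + b_{t,g} d          for t in {2, 3, 4}    (trial-of-day dummies,
                                                              drifting linearly in day)
        + u_i + sum_j v_ij B_j(d)                            (per-mouse random curve)

with B_j the natural-spline basis functions.  By default every
genotype-by-treatment group carries its own 10-parameter block (cell-means
parameterization); a shared-dummies variant pools the 6 trial-of-day
parameters across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np

from .spline import SplineBasis
from .trial_data import CohortData, ValidationError

SD_LABEL_INTERCEPT = "sd_intercept"
SD_LABEL_RESIDUAL = "sd_residual"


@dataclass
class ModelSpec:
    """Configuration of the mean model and priors.

    residual_prior: "flat_sd" mirrors the flat prior on the s.d. scale used
    for the four random-effect standard deviations; "inverse_gamma" is a
    weakly-informative IG(0.001, 0.001) alternative on the variance.
    """

    df: int = 3
    censor_limit: float = 60.0
    trials_per_day: int = 4
    groups: tuple[tuple[str, str], ...] | None = None
    group_specific_dummies: bool = True
    center_day: bool = False
    residual_prior: str = "flat_sd"

    def __post_init__(self) -> None:
        if self.residual_prior not in ("flat_sd", "inverse_gamma"):
            raise ValueError(f"unknown residual prior {self.residual_prior!r}")

    @property
    def n_groups(self) -> int:
        if self.groups is None:
            raise ValueError("groups not resolved; build the spec from a cohort first")
        return len(self.groups)

    def resolved(self, cohort: CohortData) -> "ModelSpec":
        if self.groups is not None:
            return self
        return replace(self, groups=tuple(cohort.groups))


def _group_terms(spec: ModelSpec) -> list[str]:
    terms = ["intercept"] + [f"spline{j}" for j in range(1, spec.df + 1)]
    if spec.group_specific_dummies:
        terms += _dummy_terms(spec)
    return terms


def _dummy_terms(spec: ModelSpec) -> list[str]:
    trials = range(2, spec.trials_per_day + 1)
    return [f"trial{t}" for t in trials] + [f"trial{t}_x_day" for t in trials]


def describe_parameters(spec: ModelSpec) -> list[str]:
    """Stable, documented parameter ordering shared by sampler, storage, reports.

    Fixed effects come first (group blocks in group order, then shared dummy
    terms if pooled), followed by the four random-effect standard deviations
    and the residual standard deviation.
    """
    labels: list[str] = []
    for geno, treat in spec.groups or ():
        labels += [f"{geno}:{treat}:{term}" for term in _group_terms(spec)]
    if not spec.group_specific_dummies:
        labels += [f"shared:{term}" for term in _dummy_terms(spec)]
    labels += [SD_LABEL_INTERCEPT]
    labels += [f"sd_spline{j}" for j in range(1, spec.df + 1)]
    labels += [SD_LABEL_RESIDUAL]
    return labels


def n_fixed(spec: ModelSpec) -> int:
    per_group = len(_group_terms(spec))
    shared = 0 if spec.group_specific_dummies else 2 * (spec.trials_per_day - 1)
    return per_group * spec.n_groups + shared


def fixed_row(
    day: float, trial: int, group_index: int, basis: SplineBasis, spec: ModelSpec,
    day_center: float = 0.0,
) -> np.ndarray:
    """One row of the fixed-effect design matrix for a (group, day, trial) cell."""
    p = n_fixed(spec)
    row = np.zeros(p)
    bvals = basis.evaluate(day)
    per_group = len(_group_terms(spec))
    off = group_index * per_group
    row[off] = 1.0
    row[off + 1 : off + 1 + spec.df] = bvals
    d_cov = day - day_center
    n_dum = spec.trials_per_day - 1
    if spec.group_specific_dummies:
        dum_off = off + 1 + spec.df
    else:
        dum_off = per_group * spec.n_groups
    if trial >= 2:
        row[dum_off + (trial - 2)] = 1.0
        row[dum_off + n_dum + (trial - 2)] = d_cov
    return row


@dataclass(eq=False)
class DesignMatrices:
    """Assembled design: fixed matrix, compact random design, response, censoring.

    The random design is stored compactly: ``Zrow[i]`` holds the 1 + df
    values ``(1, B_1(d_i), ..., B_df(d_i))`` and ``mouse_index[i]`` says which
    mouse's random-effect block they multiply.
    """

    X: np.ndarray
    column_labels: list[str]
    y: np.ndarray
    censored: np.ndarray
    Zrow: np.ndarray
    mouse_index: np.ndarray
    mouse_ids: list[str]
    mouse_group: np.ndarray
    basis: SplineBasis
    spec: ModelSpec
    day_center: float = 0.0
    days: list[int] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    @property
    def n_mice(self) -> int:
        return len(self.mouse_ids)

    @cached_property
    def xtx(self) -> np.ndarray:
        return self.X.T @ self.X

    @cached_property
    def xtx_chol(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.xtx)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "fixed-effect design is rank-deficient; inspect the design "
                "(empty groups, constant columns, or too few distinct days)"
            ) from exc

    @cached_property
    def ztz(self) -> np.ndarray:
        """Per-mouse Z_i' Z_i blocks, shape (n_mice, 1+df, 1+df)."""
        q = self.Zrow.shape[1]
        out = np.zeros((self.n_mice, q, q))
        outer = self.Zrow[:, :, None] * self.Zrow[:, None, :]
        np.add.at(out, self.mouse_index, outer)
        return out

    @cached_property
    def censored_idx(self) -> np.ndarray:
        return np.flatnonzero(self.censored)

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))


def build_design(cohort: CohortData, spec: ModelSpec, basis: SplineBasis) -> DesignMatrices:
    """Assemble design matrices from a validated cohort.

    Row order follows record order; permuting records permutes rows and the
    response identically.
    """
    spec = spec.resolved(cohort)
    groups = list(spec.groups)
    group_of = {g: i for i, g in enumerate(groups)}

    mouse_ids: list[str] = []
    mouse_pos: dict[str, int] = {}
    mouse_grp: list[int] = []
    for r in cohort.records:
        if r.mouse_id not in mouse_pos:
            mouse_pos[r.mouse_id] = len(mouse_ids)
            mouse_ids.append(r.mouse_id)
            mouse_grp.append(group_of[r.group])
        elif mouse_grp[mouse_pos[r.mouse_id]] != group_of[r.group]:
            raise ValidationError(f"mouse {r.mouse_id!r} has records in two groups")

    day_center = float(np.mean(cohort.days)) if spec.center_day else 0.0
    n = len(cohort.records)
    X = np.zeros((n, n_fixed(spec)))
    Zrow = np.zeros((n, 1 + spec.df))
    y = np.zeros(n)
    cens = np.zeros(n, dtype=bool)
    midx = np.zeros(n, dtype=np.intp)
    for i, r in enumerate(cohort.records):
        X[i] = fixed_row(r.day, r.trial, group_of[r.group], basis, spec, day_center)
        Zrow[i, 0] = 1.0
        Zrow[i, 1:] = basis.evaluate(r.day)
        y[i] = r.latency
        cens[i] = r.censored
        midx[i] = mouse_pos[r.mouse_id]

    labels = describe_parameters(spec)[: n_fixed(spec)]
    return DesignMatrices(
        X=X,
        column_labels=labels,
        y=y,
        censored=cens,
        Zrow=Zrow,
        mouse_index=midx,
        mouse_ids=mouse_ids,
        mouse_group=np.asarray(mouse_grp, dtype=np.intp),
        basis=basis,
        spec=spec,
        day_center=day_center,
        days=cohort.days,
    )
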