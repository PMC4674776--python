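"""End-to-end orchestration: cohort -> design -> sampler -> diagnostics -> inference.

This is the library face of the shell pipeline: one call fits the full
model with the default multi-chain protocol and returns everything the
report files contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .design import DesignMatrices, ModelSpec, build_design
from .diagnostics import DiagnosticsReport, diagnose
from .gibbs import PosteriorSamples, SamplerConfig, run_chains
from .inference import (
    ContrastResult,
    LearningCurveSummary,
    contrast,
    contrasts_to_frame,
    curves_to_frame,
    fitted_curve_draws,
    learning_rate,
    summarize_curve,
)
from .spline import SplineBasis, build_basis
from .trial_data import CohortData


@dataclass
class FitResult:
    """Everything a fitted run produces, ready to serialize."""

    cohort: CohortData
    basis: SplineBasis
    design: DesignMatrices
    samples: PosteriorSamples
    diagnostics: DiagnosticsReport
    curves: list[LearningCurveSummary] = field(default_factory=list)
    contrasts: list[ContrastResult] = field(default_factory=list)

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    def learning_rate(self, group) -> np.ndarray:
        return learning_rate(self.samples, tuple(group), self.basis, self.spec,
                             n_days=self.cohort.n_days)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.samples.save(outdir)
        self.diagnostics.to_csv(outdir / "diagnostics.csv")
        if self.curves:
            curves_to_frame(self.curves).to_csv(outdir / "curves.csv", index=False)
        if self.contrasts:
            contrasts_to_frame(self.contrasts).to_csv(outdir / "contrasts.csv", index=False)
        meta = dict(self.samples.metadata)
        meta["diagnostics"] = self.diagnostics.summary_metadata()
        with open(outdir / "metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)


def _default_contrasts(result: FitResult) -> list[ContrastResult]:
    """Learning-rate contrasts between groups sharing a genotype or treatment."""
    groups = list(result.spec.groups or ())
    rates = {g: result.learning_rate(g) for g in groups}
    out = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            if ga[0] == gb[0] or ga[1] == gb[1]:
                label = f"rate[{ga[0]}:{ga[1]}] - rate[{gb[0]}:{gb[1]}]"
                out.append(contrast(rates[ga], rates[gb], label=label))
    return out


def fit_cohort(
    cohort: CohortData,
    spec: ModelSpec | None = None,
    config: SamplerConfig | None = None,
    psrf_threshold: float = 1.1,
    with_contrasts: bool = True,
) -> FitResult:
    """Fit the hierarchical model to a cohort with the default protocol.

    Builds the 3-df natural-spline basis on the cohort's training days,
    assembles the design, runs the multi-chain Gibbs sampler, computes
    convergence diagnostics, and summarizes per-group learning curves and
    learning-rate contrasts.
    """
    spec = (spec or ModelSpec(censor_limit=cohort.censor_limit,
                              trials_per_day=cohort.trials_per_day)).resolved(cohort)
    config = config or SamplerConfig()
    basis = build_basis(np.asarray(cohort.days, dtype=float), df=spec.df)
    design = build_design(cohort, spec, basis)
    samples = run_chains(design, config)
    report = diagnose(samples, threshold=psrf_threshold)
    result = FitResult(
        cohort=cohort, basis=basis, design=design, samples=samples, diagnostics=report
    )
    for group in spec.groups or ():
        draws = fitted_curve_draws(samples, group, basis, spec, n_days=cohort.n_days)
        result.curves.append(summarize_curve(draws, group=group))
    if with_contrasts and len(spec.groups or ()) > 1:
        result.contrasts = _default_contrasts(result)
    return result
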