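"""Multi-chain convergence diagnostics: Gelman-Rubin PSRF and effective
sample size, computed per model parameter after a fit."""

from mazelearn import GroupCurve, SamplerConfig, TrueParameters, fit_cohort, simulate_cohort

truth = TrueParameters(
    groups=(("WT", "scr"),),
    curves=(GroupCurve(45.0, 1.2),),
    mice_per_group=(12,),
    seed=8,
)
cohort, _ = simulate_cohort(truth)
result = fit_cohort(
    cohort,
    config=SamplerConfig(n_chains=3, burn_in=400, draws_per_chain=600, base_seed=8),
    with_contrasts=False,
)

report = result.diagnostics
print(report.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nmax PSRF {report.max_psrf:.3f} -> "
      f"{'converged' if report.converged else 'NOT converged'} at threshold "
      f"{report.threshold}")
print("PSRF near 1 means between-chain and within-chain variability agree;")
print("ESS is the number of independent draws the autocorrelated chain is worth.")
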