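# Methods

## Model

One censored Gaussian hierarchical regression is fit jointly to all trials
of all mice.  For mouse *i* in genotype-by-treatment group *g*, day *d*
(1-based), trial-of-day *t* (1..4):

    y*_idt = x'_gdt β + u_i + Σ_j v_ij B_j(d) + ε_idt,    ε ~ N(0, σ²)

* **Group mean structure** (10 parameters per group, cell-means
  parameterization): intercept; three natural-cubic-spline terms B₁..B₃ in
  training day; dummies for trials 2–4; and dummy×day interactions so the
  trial-of-day effects drift linearly over training.  Groups share no fixed
  effects by default (`ModelSpec.group_specific_dummies=False` pools the six
  trial-of-day parameters across groups).
* **Spline basis**: df = 3; boundary knots at the min/max observed day,
  internal knots at the 1/3 and 2/3 quantiles of the observed day values.
  The basis is built from truncated power functions with the standard
  natural-spline reduction and each basis function is affinely rescaled to
  run 0 at the first day to 1 at the last.  The rescaling changes no fitted
  value (the model has a free intercept; the spanned space is identical) but
  puts the spline coefficients — fixed and random — in seconds-of-change
  across training, which is what makes a "2 s" random-spline standard
  deviation meaningful.  Knots and scaling constants are serialized in the
  run metadata.
* **Spline covariate is training day**, not cumulative trial index: the
  trial-of-day dummies already carry the within-day structure, so the spline
  only has to describe the day-level trajectory.
* **Random effects**: per mouse, an intercept u_i and three spline
  coefficients v_i1..3, independent zero-mean Gaussians with standard
  deviations σ_u, σ_v1..σ_v3 (the model's four variance components), shared
  across groups (one joint model).
* **Censoring**: observed latency is min(y*, 60 s) plus a flag.  The
  Gaussian latent scale is unbounded below; real latencies are not, which is
  a known approximation of this model class (see Limitations).
* **Priors**: flat on all fixed effects; flat on the standard-deviation
  scale for the four random-effect s.d.s, giving inverse-gamma variance
  conditionals with shape (M−1)/2 for M mice; residual s.d. flat on the
  s.d. scale by default (`ModelSpec.residual_prior="inverse_gamma"` switches
  to IG(0.001, 0.001) on the variance).  Flat s.d. priors are improper, so
  the sampler refuses cohorts with fewer than 3 mice.

## Sampler

Blocked Gibbs with Tobit-style data augmentation.  Each sweep, in fixed
order:

1. **Latent responses** — for every censored row, y* is redrawn from
   N(fitted, σ²) truncated to [60, ∞).  Truncated draws invert the upper-tail
   CDF (`ndtri` on u·Φ̄(α)), which is stable arbitrarily far into the tail;
   if the tail mass underflows entirely, an exponential tail approximation
   takes over.
2. **Fixed effects** — one joint Gaussian draw,
   N((X'X)⁻¹X'r, σ²(X'X)⁻¹), with r the latent response minus
   random-effect contributions; X'X is Cholesky-factored once per fit.
3. **Random effects** — each mouse's 4-vector from its exact Gaussian
   conditional; mice are conditionally independent and drawn in one batched
   Cholesky pass.
4. **Variance components** — inverse-gamma conditionals as above; the
   residual variance analogously with shape (n−1)/2.  Scale parameters are
   floored at 1e-12 (logged) to survive all-zero random-effect states early
   in burn-in.
5. **Scale interweaving** — an ancillarity–sufficiency move: holding each
   random-effect family's whitened values w = b/σ fixed, the scale σ is a
   regression coefficient with a truncated-Gaussian conditional and is
   redrawn jointly with the family.  This is an exact move that leaves the
   posterior invariant; without it the spline variance components mix very
   slowly (ESS ≈ 11 per 2,500-draw chain, versus ≈ 80–200 with it), which is
   the classic funnel of scale/effect Gibbs alternation.  It can be disabled
   (`SamplerConfig.interweave=False`).

**Protocol defaults**: 3 chains; 2,500 burn-in + 2,500 retained sweeps per
chain; overdispersed starts (chain c multiplies the least-squares fixed
effects and heuristic initial s.d.s by 0.5, 1.0, 2.0 for c = 0, 1, 2);
chains are concatenated chain-major and thinned by dropping every combined
index ≡ 2 (mod 3), 7,500 → exactly 5,000 inference draws (an evenly spaced
subset is used for non-default counts).  Each chain owns an RNG stream
derived deterministically from (base seed, chain index), so serial and
chain-parallel execution agree and every run is bit-reproducible.  Draws are
stored per chain for diagnostics; inference uses the combined thinned set.
Latent responses and per-mouse random effects are not serialized.

## Diagnostics

* **Gelman-Rubin PSRF** (original, non-split): √((n−1)/n + B/(nW)); a split
  variant is available behind a flag.  W = 0 with B > 0 reports +∞; W = B = 0
  reports 1.
* **Effective sample size**: n/τ with τ from Geyer's initial positive
  sequence (autocorrelations summed in consecutive pairs until the first
  non-positive pair).  Constant chains report ESS = n; anticorrelated chains
  may report ESS > n.
* `diagnose` covers every labelled parameter, declares convergence when all
  PSRF ≤ 1.1 (default), and also reports PSRFs rounded to one decimal.

## Inference definitions

All curve-level quantities use the population fitted curve (random effects
at zero) on the full day×trial grid; per-draw evaluation preserves posterior
dependence, and bands are 2.5–97.5 percentiles.

* **Learning rate (s/trial)**: the least-squares slope of the fitted curve
  against cumulative trial index (1..24), sign-flipped so positive =
  improvement.  For a curve linear in cumulative trial this equals the
  endpoint difference divided by 23, but it uses all 24 cells: across
  replicate 20-mouse cohorts the endpoint version's estimates spread ~1.8×
  wider (s.d. 0.138 vs 0.078 s/trial), so the slope is the default and
  `method="endpoint"` remains available.
* **Within-day improvement at day d**: trial-4 dummy plus its drift, a₄+b₄d
  (negative = faster later in the day).
* **Inter-day setback**: mean over consecutive-day transitions of
  fitted(d+1, trial 1) − fitted(d, trial 4); a day range restricts the
  transitions (e.g. the last 3 training days = the last two transitions).
* **Contrasts**: draw-matched differences; P = 2·min(tail fractions), with
  "< 2/N" reported when a tail is empty.  Interval endpoints use symmetric
  order statistics (the ⌈0.025 n⌉-th draw from each end) so that "P < 0.05"
  and "the 95% interval excludes 0" agree exactly for continuous draws.

## Synthetic cohorts

The generator mirrors the model: group mean = start latency − rate ×
cumulative trial (optionally plus trial offsets/drifts), per-mouse random
intercept and spline coefficients on the same normalized basis, Gaussian
noise, censoring at 60 s.  Defaults emulate the study conditions: 4 groups,
18–28 mice/group (the packaged study-scale scenario uses 26/28/18/24), 6
days × 4 trials, start 45 s, group rates 1.6/0.9/1.6/0.4 s/trial, residual
s.d. 10 s, intercept s.d. 5 s, spline s.d.s 2 s.  The noise scales are
package choices producing realistic early-training censoring (~6% on day 1),
not study-reported values, and are labelled as such.

Because the latent scale is Gaussian, simulated latencies can go below zero
late in training when the mean approaches the floor of the scale; they are
recorded as-is so the generator and the likelihood share one law (this is
what makes parameter recovery exact).  Real latencies are bounded below by
swim time, so the generator does not emulate floor effects, nor thigmotaxis,
search-strategy switching, or swim-speed differences.  Passing recovery and
calibration tests therefore shows the *inference machinery* is correct under
the model's own assumptions — not that the model is correct for any given
real cohort.  File loading enforces positive latencies for empirical data
(`load_trials(..., require_positive=True)`, the default); in-memory and
pipeline-simulated cohorts are exempt.

The generating group curves lie exactly in the span of the fixed-effect
design, so the truth for recovery/coverage tests is the (exact)
least-squares projection of the noiseless cell means.

## Numerical choices

* Variance-draw scales floored at 1e-12 (logged when triggered).
* Truncated-normal sampling via upper-tail CDF inversion; exponential
  fallback when the tail mass underflows; results clipped to the bound.
* Design rank is checked via Cholesky of X'X at initialization; rank
  deficiency raises an error pointing at the design.
* Degenerate diagnostics inputs (constant chains) are defined explicitly
  rather than returning NaN (see Diagnostics).
* Ties at exactly zero in contrast draws would break the CI/P equivalence;
  posterior draws are continuous so this is not guarded.

## Problem sizes

The default test suite runs scaled configurations chosen to keep the full
suite under a few minutes: shared fixtures use 2 chains × (300 + 500) sweeps
on 8–16-mouse cohorts; the calibration checks use 50 null replicates at
2 × (200 + 300) sweeps and 20 coverage replicates at 2 × (250 + 350); the
acceptance checks run the full published protocol (3 × (2,500 + 2,500)) on
the study-scale cohort and on the 20-mouse recovery cohorts.
`scripts/acceptance.py` runs the full protocol three times (~30–40 s total).

## Limitations

* The Gaussian latent scale ignores the physical lower bound of latencies
  and any skew; the model is the study's, reimplemented, not a proposal for
  a better one.
* Variance components are shared across groups; per-group variances are out
  of scope.
* Flat s.d. priors make small-M behavior delicate; the M ≥ 3 guard is a
  propriety heuristic, not a proof, and posteriors from very small cohorts
  should be treated with suspicion.
* The non-split PSRF can miss within-chain trends that split-R̂ would flag;
  the split variant is available but not the default reported statistic.
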