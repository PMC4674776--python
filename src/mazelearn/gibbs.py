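"""Blocked Gibbs sampler for the censored hierarchical latency model.

The latent-variable trick makes every full conditional Gaussian or
inverse-gamma: each censored observation carries a latent uncensored latency
``y*`` that is resampled every sweep from a Gaussian truncated to
``[censor_limit, inf)``, after which the model is an ordinary Gaussian
linear mixed model and the blocks

    latent y*  ->  fixed effects beta  ->  per-mouse random effects
               ->  variance components

are each drawn exactly.  Fixed effects have flat priors; the four
random-effect standard deviations (intercept plus three spline terms) have
flat priors on the s.d. scale, giving inverse-gamma conditionals with shape
(M - 1)/2 for M mice; the residual s.d. prior is configurable (flat on the
s.d. scale by default).

Multiple chains are started from overdispersed initial values, each with an
independent deterministic RNG stream, so runs are bit-reproducible from the
base seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import solve_triangular
from scipy.special import ndtr, ndtri

from .design import DesignMatrices, describe_parameters

logger = logging.getLogger("mazelearn.gibbs")

_VAR_FLOOR = 1e-12


def sample_truncnorm_lower(rng, mu, sigma, lower):
    """Draw from Normal(mu, sigma^2) truncated to [lower, inf), vectorized.

    Uses inverse-CDF sampling on the upper tail (numerically stable far into
    the tail, where the naive CDF inversion saturates), with an exponential
    tail approximation as a last resort when the tail mass underflows.
    """
    mu = np.asarray(mu, dtype=float)
    alpha = (lower - mu) / sigma
    p = ndtr(-alpha)  # upper tail mass beyond the bound
    u = rng.uniform(size=alpha.shape)
    w = u * p
    z = np.empty_like(alpha)
    ok = w > 0
    z[ok] = -ndtri(w[ok])
    if not ok.all():
        bad = ~ok
        a = np.maximum(alpha[bad], 1.0)
        z[bad] = alpha[bad] + rng.exponential(size=int(bad.sum())) / a
    out = mu + sigma * z
    return np.maximum(out, lower)


@dataclass
class SamplerConfig:
    """Chain counts and reproducibility knobs.

    Defaults mirror the study protocol: 3 chains, 2,500 burn-in sweeps and
    2,500 retained sweeps each, combined chain-major and deterministically
    thinned to 5,000 draws for inference.  ``overdispersion`` gives the
    per-chain multiplicative jitter applied to the least-squares start.
    ``fixed_sds`` pins named standard deviations (e.g. for oracle tests);
    pinned families skip their variance update.
    """

    n_chains: int = 3
    burn_in: int = 2500
    draws_per_chain: int = 2500
    thin_target: int | None = 5000
    base_seed: int = 0
    overdispersion: tuple[float, ...] = (0.5, 1.0, 2.0)
    fixed_sds: dict[str, float] | None = None
    interweave: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.burn_in < 0 or self.draws_per_chain < 1:
            raise ValueError("chain counts must be positive (burn_in may be 0)")

    def to_metadata(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "burn_in": self.burn_in,
            "draws_per_chain": self.draws_per_chain,
            "thin_target": self.thin_target,
            "base_seed": self.base_seed,
            "overdispersion": list(self.overdispersion),
            "fixed_sds": dict(self.fixed_sds) if self.fixed_sds else None,
            "interweave": self.interweave,
        }


@dataclass
class ChainState:
    """All sampled quantities of one chain at one sweep."""

    beta: np.ndarray          # fixed effects, length p
    b: np.ndarray             # per-mouse random effects, (n_mice, 1 + df)
    ystar: np.ndarray         # latent responses, length n_obs
    sd_intercept: float
    sd_spline: np.ndarray     # length df
    sd_residual: float
    rng: np.random.Generator
    fixed_sds: frozenset[str] = field(default_factory=frozenset)

    def sds(self) -> np.ndarray:
        return np.concatenate(([self.sd_intercept], self.sd_spline, [self.sd_residual]))

    def fitted(self, design: DesignMatrices) -> np.ndarray:
        return design.X @ self.beta + (design.Zrow * self.b[design.mouse_index]).sum(axis=1)

    def validate(self, design: DesignMatrices) -> None:
        assert self.sd_residual > 0 and self.sd_intercept > 0 and (self.sd_spline > 0).all()
        idx = design.censored_idx
        assert (self.ystar[idx] >= design.spec.censor_limit - 1e-9).all()
        unc = ~design.censored
        assert np.array_equal(self.ystar[unc], design.y[unc])


def init_chain(design: DesignMatrices, config: SamplerConfig, chain_index: int) -> ChainState:
    """Initialize a chain: least-squares start with chain-indexed jitter.

    Censored rows are treated at the cutoff for the least-squares solve; the
    chain's fixed effects and initial standard deviations are scaled by the
    chain's overdispersion factor; latent responses start just above the
    cutoff for censored rows.  The RNG stream derives deterministically from
    (base_seed, chain_index).
    """
    L = design.xtx_chol  # raises on rank deficiency
    xty = design.X.T @ design.y
    beta_ls = solve_triangular(L.T, solve_triangular(L, xty, lower=True), lower=False)
    resid = design.y - design.X @ beta_ls
    dof = max(design.n_obs - design.n_params, 1)
    s0 = max(float(np.sqrt((resid**2).sum() / dof)), 1e-3)

    factor = config.overdispersion[chain_index % len(config.overdispersion)]
    fixed = dict(config.fixed_sds or {})
    df = design.spec.df
    sd_spline = np.array(
        [fixed.get(f"sd_spline{j}", s0 / 4.0 * factor) for j in range(1, df + 1)]
    )
    ystar = design.y.copy()
    ystar[design.censored_idx] = design.spec.censor_limit + 1.0

    return ChainState(
        beta=beta_ls * factor,
        b=np.zeros((design.n_mice, 1 + df)),
        ystar=ystar,
        sd_intercept=fixed.get("sd_intercept", s0 / 2.0 * factor),
        sd_spline=sd_spline,
        sd_residual=fixed.get("sd_residual", s0 * factor),
        rng=np.random.default_rng([int(config.base_seed), int(chain_index)]),
        fixed_sds=frozenset(fixed),
    )


def update_latent(state: ChainState, design: DesignMatrices) -> ChainState:
    """Redraw latent responses for censored rows from their truncated-normal
    full conditionals; uncensored rows are untouched."""
    idx = design.censored_idx
    if idx.size == 0:
        return state
    mu = state.fitted(design)[idx]
    state.ystar[idx] = sample_truncnorm_lower(
        state.rng, mu, state.sd_residual, design.spec.censor_limit
    )
    return state


def update_fixed_effects(state: ChainState, design: DesignMatrices) -> ChainState:
    """Draw beta from its Gaussian full conditional under the flat prior:
    N( (X'X)^{-1} X'r , sigma^2 (X'X)^{-1} ) with r the latent response net
    of random-effect contributions."""
    r = state.ystar - (design.Zrow * state.b[design.mouse_index]).sum(axis=1)
    L = design.xtx_chol
    mean = solve_triangular(L.T, solve_triangular(L, design.X.T @ r, lower=True), lower=False)
    z = state.rng.standard_normal(design.n_params)
    state.beta = mean + state.sd_residual * solve_triangular(L.T, z, lower=False)
    return state


def update_random_effects(state: ChainState, design: DesignMatrices) -> ChainState:
    """Jointly redraw each mouse's (intercept, spline coefficients) block.

    Mice are conditionally independent, so the (1+df)-dimensional Gaussian
    conditionals are drawn in one batched Cholesky pass.
    """
    resid = state.ystar - design.X @ state.beta
    q = design.Zrow.shape[1]
    rhs = np.zeros((design.n_mice, q))
    np.add.at(rhs, design.mouse_index, design.Zrow * resid[:, None])
    sigma2 = state.sd_residual**2
    d_inv = np.concatenate(([state.sd_intercept**-2], state.sd_spline**-2.0))
    A = design.ztz / sigma2 + np.diag(d_inv)[None, :, :]
    mean = np.linalg.solve(A, (rhs / sigma2)[..., None])[..., 0]
    Lb = np.linalg.cholesky(A)
    z = state.rng.standard_normal((design.n_mice, q))
    # solve L^T x = z  =>  cov(x) = A^{-1}
    state.b = mean + np.linalg.solve(np.swapaxes(Lb, 1, 2), z[..., None])[..., 0]
    return state


def _draw_variance_flat_sd(rng, ss: float, m: int) -> float:
    """Variance draw under a flat prior on the s.d.: inverse-gamma with
    shape (m - 1)/2 and scale ss/2, via a scale-free gamma draw."""
    return (ss / 2.0) / rng.gamma((m - 1) / 2.0)


def update_variance_components(state: ChainState, design: DesignMatrices) -> ChainState:
    """Redraw the four random-effect s.d.s and the residual s.d.

    Flat priors on the s.d. scale give inverse-gamma conditionals with shape
    (M - 1)/2 and scale (sum of squared effects)/2.  A small positive floor
    on the scale guards all-zero random-effect states early in burn-in.
    M < 3 mice is refused: the flat s.d. prior then risks an improper
    posterior.
    """
    m = design.n_mice
    updatable = {"sd_intercept", "sd_residual"} | {
        f"sd_spline{j}" for j in range(1, design.spec.df + 1)
    }
    to_update = updatable - state.fixed_sds
    if (to_update - {"sd_residual"}) and m < 3:
        raise ValueError(
            f"only {m} mice: flat priors on random-effect s.d.s risk an improper "
            "posterior with fewer than 3 mice; pin the s.d.s or enlarge the cohort"
        )

    def _scale(ss: float, what: str) -> float:
        if ss < _VAR_FLOOR:
            logger.warning("variance-draw scale for %s floored at %g", what, _VAR_FLOOR)
            return _VAR_FLOOR
        return ss

    if "sd_intercept" in to_update:
        ss = _scale(float((state.b[:, 0] ** 2).sum()), "sd_intercept")
        state.sd_intercept = float(np.sqrt(_draw_variance_flat_sd(state.rng, ss, m)))
    for j in range(1, design.spec.df + 1):
        if f"sd_spline{j}" in to_update:
            ss = _scale(float((state.b[:, j] ** 2).sum()), f"sd_spline{j}")
            state.sd_spline[j - 1] = float(np.sqrt(_draw_variance_flat_sd(state.rng, ss, m)))
    if "sd_residual" in to_update:
        resid = state.ystar - state.fitted(design)
        ss = _scale(float((resid**2).sum()), "sd_residual")
        n = design.n_obs
        if design.spec.residual_prior == "flat_sd":
            var = _draw_variance_flat_sd(state.rng, ss, n)
        else:  # weakly-informative inverse-gamma(0.001, 0.001)
            var = (0.001 + ss / 2.0) / state.rng.gamma(0.001 + n / 2.0)
        state.sd_residual = float(np.sqrt(var))
    return state


def interweave_scales(state: ChainState, design: DesignMatrices) -> ChainState:
    """Ancillarity-sufficiency interweaving move for the random-effect scales.

    Plain Gibbs alternation between a random-effect family and its standard
    deviation mixes slowly when the per-mouse effects are weakly identified
    (the well-known funnel).  This extra exact move redraws each family's
    scale jointly with the family: holding the whitened effects w = b_j /
    sd_j fixed, the scale is a regression coefficient on the predictor
    w * Zcol_j with a flat positive prior, i.e. a truncated-Gaussian full
    conditional.  The stationary distribution is unchanged; mixing of the
    variance components improves by orders of magnitude.
    """
    q = design.Zrow.shape[1]
    labels = ["sd_intercept"] + [f"sd_spline{j}" for j in range(1, q)]
    sds = [state.sd_intercept] + list(state.sd_spline)
    contrib = design.Zrow * state.b[design.mouse_index]  # per-row, per-family
    base = state.ystar - design.X @ state.beta - contrib.sum(axis=1)
    sigma2 = state.sd_residual**2
    for j, label in enumerate(labels):
        if label in state.fixed_sds:
            continue
        old_sd = sds[j]
        if old_sd <= 0:
            continue
        pred = contrib[:, j] / old_sd  # = w_{mouse(i)} * Zrow[i, j]
        ptp = float(pred @ pred)
        if ptp < 1e-12:
            continue
        r = base + contrib[:, j]  # residual with family j excluded
        m = float(pred @ r) / ptp
        s = float(np.sqrt(sigma2 / ptp))
        new_sd = float(sample_truncnorm_lower(state.rng, np.array(m), s, 0.0))
        new_sd = max(new_sd, np.sqrt(_VAR_FLOOR))
        ratio = new_sd / old_sd
        state.b[:, j] *= ratio
        contrib[:, j] *= ratio
        if j == 0:
            state.sd_intercept = new_sd
        else:
            state.sd_spline[j - 1] = new_sd
        sds[j] = new_sd
    return state


def sweep(state: ChainState, design: DesignMatrices, interweave: bool = True) -> ChainState:
    """One full Gibbs sweep in the fixed update order."""
    update_latent(state, design)
    update_fixed_effects(state, design)
    update_random_effects(state, design)
    update_variance_components(state, design)
    if interweave:
        interweave_scales(state, design)
    idx = design.censored_idx
    assert idx.size == 0 or (state.ystar[idx] >= design.spec.censor_limit - 1e-9).all()
    return state


def thin_indices(total: int, target: int | None) -> np.ndarray:
    """Deterministic thinning of the chain-major combined draws.

    When the combined count is exactly 1.5x the target (the default 7,500 ->
    5,000), every combined index congruent to 2 (mod 3) is dropped; otherwise
    an evenly spaced deterministic subset of ``target`` indices is kept.
    """
    if target is None or total <= target:
        return np.arange(total)
    if 2 * total == 3 * target:
        return np.flatnonzero(np.arange(total) % 3 != 2)
    return np.floor(np.arange(target) * (total / target)).astype(int)


@dataclass(eq=False)
class PosteriorSamples:
    """Labelled retained draws across chains, plus run metadata.

    ``draws`` has shape (n_chains, draws_per_chain, n_params) with parameter
    order given by ``labels`` (fixed effects, then the five standard
    deviations).  Diagnostics use the per-chain arrays; inference uses the
    combined, thinned draws.
    """

    draws: np.ndarray
    labels: list[str]
    metadata: dict

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown parameter {label!r}; known: {self.labels}") from None

    def get(self, label: str) -> np.ndarray:
        """Per-chain draws for one parameter, shape (n_chains, draws_per_chain)."""
        return self.draws[:, :, self.index_of(label)]

    def combined(self) -> np.ndarray:
        """Chain-major concatenation, shape (n_chains * draws_per_chain, n_params)."""
        c, i, p = self.draws.shape
        return self.draws.reshape(c * i, p)

    def thinned(self) -> np.ndarray:
        """The inference draw set: combined chain-major, deterministically thinned."""
        combined = self.combined()
        idx = thin_indices(combined.shape[0], self.metadata.get("thin_target"))
        return combined[idx]

    @property
    def n_retained(self) -> int:
        return self.thinned().shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        c, i, p = self.draws.shape
        df = pd.DataFrame(self.combined(), columns=self.labels)
        df.insert(0, "iteration", np.tile(np.arange(i), c))
        df.insert(0, "chain", np.repeat(np.arange(c), i))
        return df

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / "draws.csv", index=False)
        with open(outdir / "metadata.yaml", "w") as fh:
            yaml.safe_dump(self.metadata, fh, sort_keys=False)

    @classmethod
    def load(cls, outdir) -> "PosteriorSamples":
        from pathlib import Path

        outdir = Path(outdir)
        df = pd.read_csv(outdir / "draws.csv")
        with open(outdir / "metadata.yaml") as fh:
            metadata = yaml.safe_load(fh)
        labels = [c for c in df.columns if c not in ("chain", "iteration")]
        chains = sorted(df["chain"].unique())
        draws = np.stack(
            [df.loc[df["chain"] == c, labels].to_numpy() for c in chains]
        )
        return cls(draws=draws, labels=labels, metadata=metadata)


def run_chains(design: DesignMatrices, config: SamplerConfig) -> PosteriorSamples:
    """Run the full multi-chain protocol and return labelled retained draws.

    Each chain: overdispersed init, ``burn_in`` sweeps, then
    ``draws_per_chain`` retained sweeps recording the fixed effects and the
    five standard deviations.  Fully reproducible from the base seed; chains
    own independent RNG streams, so serial and chain-parallel execution
    agree.
    """
    spec = design.spec
    labels = describe_parameters(spec)
    p = design.n_params
    n_sd = 2 + spec.df
    if len(labels) != p + n_sd:
        raise ValueError("parameter labels inconsistent with design")

    fixed = dict(config.fixed_sds or {})
    updates_random_sds = any(
        lab not in fixed for lab in labels[p : p + 1 + spec.df]
    )
    if updates_random_sds and design.n_mice < 3:
        raise ValueError(
            f"only {design.n_mice} mice: flat priors on random-effect s.d.s risk an "
            "improper posterior with fewer than 3 mice"
        )

    draws = np.empty((config.n_chains, config.draws_per_chain, p + n_sd))
    chain_seeds = []
    for c in range(config.n_chains):
        state = init_chain(design, config, c)
        chain_seeds.append([int(config.base_seed), c])
        for s in range(config.burn_in):
            sweep(state, design, interweave=config.interweave)
        for s in range(config.draws_per_chain):
            sweep(state, design, interweave=config.interweave)
            draws[c, s, :p] = state.beta
            draws[c, s, p:] = state.sds()
            if not np.isfinite(draws[c, s]).all():
                raise RuntimeError(
                    f"non-finite sampler state in chain {c} at retained sweep {s}"
                )
        logger.info("chain %d finished (%d + %d sweeps)", c, config.burn_in,
                    config.draws_per_chain)

    total = config.n_chains * config.draws_per_chain
    kept = len(thin_indices(total, config.thin_target))
    metadata = {
        "config": config.to_metadata(),
        "thin_target": config.thin_target,
        "n_retained_inference": int(kept),
        "chain_seeds": chain_seeds,
        "parameter_order": labels,
        "knots": design.basis.to_metadata(),
        "groups": [list(g) for g in (spec.groups or [])],
        "priors": {
            "fixed_effects": "flat",
            "random_effect_sds": "flat on the s.d. scale",
            "residual": spec.residual_prior,
        },
        "thin_rule": "chain-major concatenation; drop combined indices == 2 (mod 3) "
                     "when total = 1.5 * target, else evenly spaced subset",
        "n_obs": int(design.n_obs),
        "n_mice": int(design.n_mice),
        "spec": {
            "df": spec.df,
            "censor_limit": spec.censor_limit,
            "trials_per_day": spec.trials_per_day,
            "group_specific_dummies": spec.group_specific_dummies,
            "center_day": spec.center_day,
        },
    }
    return PosteriorSamples(draws=draws, labels=labels, metadata=metadata)
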