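"""Independent oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
package: the natural spline is built by imposing linear-tail constraints on
a full cubic truncated-power basis; posteriors are computed by dense grid
integration; truncated-normal moments come from the closed form.
"""

from __future__ import annotations

import numpy as np

from mazelearn.design import DesignMatrices, ModelSpec
from mazelearn.gibbs import ChainState
from mazelearn.spline import build_basis


# -- natural cubic spline by explicit constraint solving -------------------

def natural_spline_oracle(knots):
    """Return callables spanning the non-constant natural cubic spline space.

    The space of cubic splines with the given knots that are linear beyond
    both boundary knots is {a + b x + sum_i e_i (x - k_i)_+^3} subject to
    sum_i e_i = 0 and sum_i e_i k_i = 0 (zero second and third derivative to
    the right of the last knot; truncated powers already vanish to the
    left).  Dimension = 2 + (K - 2); beyond the intercept this yields K - 1
    functions: x itself plus a null-space basis of the e-constraints.
    """
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    C = np.stack([np.ones(K), knots])        # (2, K) constraint matrix on e
    _, _, vt = np.linalg.svd(C)
    null = vt[2:].T                          # (K, K-2) null-space basis

    def make(coefs):
        def f(x):
            x = np.asarray(x, dtype=float)
            tp = np.maximum(x[..., None] - knots, 0.0) ** 3
            return tp @ coefs
        return f

    funcs = [lambda x: np.asarray(x, dtype=float)]
    funcs += [make(null[:, m]) for m in range(null.shape[1])]
    return funcs


def oracle_design_matrix(funcs, x):
    x = np.asarray(x, dtype=float)
    return np.column_stack([np.ones_like(x)] + [f(x) for f in funcs])


# -- grid-integration posteriors ------------------------------------------

def grid_posterior(logpost, grid):
    """Normalize a log-density on a 1-D grid; return (mean, sd, cdf, grid)."""
    lp = np.asarray([logpost(g) for g in grid], dtype=float)
    w = np.exp(lp - lp.max())
    w /= np.trapezoid(w, grid)
    mean = np.trapezoid(w * grid, grid)
    var = np.trapezoid(w * (grid - mean) ** 2, grid)
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    return mean, np.sqrt(var), cdf, grid


def grid_quantile(cdf, grid, q):
    return float(np.interp(q, cdf, grid))


# -- truncated normal closed forms ----------------------------------------

def truncnorm_lower_mean(mu, sigma, lower):
    from scipy.stats import norm

    alpha = (lower - mu) / sigma
    lam = norm.pdf(alpha) / norm.sf(alpha)
    return mu + sigma * lam


def truncnorm_lower_sd(mu, sigma, lower):
    from scipy.stats import norm

    alpha = (lower - mu) / sigma
    lam = norm.pdf(alpha) / norm.sf(alpha)
    return sigma * np.sqrt(1 + alpha * lam - lam**2)


# -- hand-built sampler fixtures ------------------------------------------

def manual_design(X, y, censored, mouse_index=None, Zrow=None, censor_limit=60.0):
    """A DesignMatrices assembled by hand for single-block oracle tests."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    spec = ModelSpec(groups=(("G", "x"),), censor_limit=censor_limit)
    basis = build_basis(np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]), df=spec.df)
    if Zrow is None:
        Zrow = np.zeros((n, 1 + spec.df))
    if mouse_index is None:
        mouse_index = np.zeros(n, dtype=np.intp)
    n_mice = int(np.max(mouse_index)) + 1
    return DesignMatrices(
        X=X,
        column_labels=[f"b{j}" for j in range(X.shape[1])],
        y=y,
        censored=np.asarray(censored, dtype=bool),
        Zrow=np.asarray(Zrow, dtype=float),
        mouse_index=np.asarray(mouse_index, dtype=np.intp),
        mouse_ids=[f"m{i}" for i in range(n_mice)],
        mouse_group=np.zeros(n_mice, dtype=np.intp),
        basis=basis,
        spec=spec,
    )


def make_state(design, beta, sd_residual=1.0, sd_intercept=1.0,
               sd_spline=(1.0, 1.0, 1.0), seed=0, fixed=()):
    ystar = design.y.copy()
    ystar[design.censored_idx] = design.spec.censor_limit + 1.0
    return ChainState(
        beta=np.atleast_1d(np.asarray(beta, dtype=float)),
        b=np.zeros((design.n_mice, design.Zrow.shape[1])),
        ystar=ystar,
        sd_intercept=float(sd_intercept),
        sd_spline=np.asarray(sd_spline, dtype=float),
        sd_residual=float(sd_residual),
        rng=np.random.default_rng(seed),
        fixed_sds=frozenset(fixed),
    )


def gls_posterior_mean(X, y, Zblocks, D, sigma2):
    """Flat-prior GLS posterior mean of beta with marginal covariance
    sigma2 I + Z D Z' assembled from per-mouse blocks."""
    n = len(y)
    V = sigma2 * np.eye(n)
    for rows, Zi in Zblocks:
        V[np.ix_(rows, rows)] += Zi @ D @ Zi.T
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    return np.linalg.solve(A, X.T @ Vi @ y)
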