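"""Natural cubic spline basis over training day.

A natural cubic spline with ``df`` degrees of freedom (beyond the intercept)
is piecewise cubic with continuous second derivatives, linear at and beyond
the boundary knots, with ``df - 1`` internal knots.  The basis is built from
truncated power functions via the standard reduction

    d_k(x) = [ (x - k_k)_+^3 - (x - k_K)_+^3 ] / (k_K - k_k)

    basis  = { x,  d_1 - d_{K-1},  ...,  d_{K-2} - d_{K-1} }

where k_1 < ... < k_K are the knots (boundary plus internal).  Each basis
function is then affinely rescaled to run from 0 at the lower boundary knot
to 1 at the upper boundary knot, so that a regression coefficient on any
basis column reads directly as "seconds of change across the training
window".  Rescaling does not alter the spanned function space (the model
always carries a separate intercept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ConfigurationError(ValueError):
    """The requested basis cannot be built from the supplied day values."""


def _truncated_cubic(t: np.ndarray) -> np.ndarray:
    return np.maximum(t, 0.0) ** 3


@dataclass(frozen=True)
class SplineBasis:
    """Evaluable natural cubic spline basis (see module docstring).

    ``scale`` / ``offset`` hold the per-function affine normalization:
    column j of the raw truncated-power basis ``B_raw`` is reported as
    ``(B_raw_j(x) - offset_j) / scale_j``.
    """

    df: int
    boundary_knots: tuple[float, float]
    internal_knots: tuple[float, ...]
    offset: tuple[float, ...]
    scale: tuple[float, ...]

    @property
    def knots(self) -> np.ndarray:
        """All knots in increasing order: lower boundary, internal, upper."""
        return np.array(
            [self.boundary_knots[0], *self.internal_knots, self.boundary_knots[1]]
        )

    def _raw(self, day: np.ndarray) -> np.ndarray:
        x = np.asarray(day, dtype=float)
        knots = self.knots
        K = len(knots)
        cols = [x]
        if K >= 3:
            last = (_truncated_cubic(x - knots[-2]) - _truncated_cubic(x - knots[-1])) / (
                knots[-1] - knots[-2]
            )
            for k in range(K - 2):
                dk = (_truncated_cubic(x - knots[k]) - _truncated_cubic(x - knots[-1])) / (
                    knots[-1] - knots[k]
                )
                cols.append(dk - last)
        return np.stack(cols, axis=-1)

    def evaluate(self, day) -> np.ndarray:
        """Basis values at ``day``; shape ``day.shape + (df,)``.

        Defined for any real day: functions are linear beyond the boundary
        knots (natural-spline extrapolation).
        """
        raw = self._raw(np.asarray(day, dtype=float))
        return (raw - np.asarray(self.offset)) / np.asarray(self.scale)

    def to_metadata(self) -> dict:
        return {
            "df": self.df,
            "boundary_knots": [float(v) for v in self.boundary_knots],
            "internal_knots": [float(v) for v in self.internal_knots],
            "offset": [float(v) for v in self.offset],
            "scale": [float(v) for v in self.scale],
            "normalization": "each basis function 0 at lower, 1 at upper boundary knot",
        }

    @classmethod
    def from_metadata(cls, meta: dict) -> "SplineBasis":
        return cls(
            df=int(meta["df"]),
            boundary_knots=tuple(meta["boundary_knots"]),
            internal_knots=tuple(meta["internal_knots"]),
            offset=tuple(meta["offset"]),
            scale=tuple(meta["scale"]),
        )


def build_basis(days, df: int = 3) -> SplineBasis:
    """Build the natural cubic spline basis for the observed day values.

    Boundary knots sit at the min and max observed day; the ``df - 1``
    internal knots sit at evenly spaced quantiles of the supplied values
    (e.g. the 33.3% and 66.7% quantiles for ``df = 3``).
    """
    days = np.asarray(days, dtype=float)
    distinct = np.unique(days)
    if df < 1:
        raise ConfigurationError(f"df must be >= 1, got {df}")
    if len(distinct) < df + 1:
        raise ConfigurationError(
            f"need at least df + 1 = {df + 1} distinct day values, got {len(distinct)}"
        )
    lo, hi = float(distinct[0]), float(distinct[-1])
    qs = np.arange(1, df) / df
    internal = np.quantile(days, qs)
    if np.any(internal <= lo) or np.any(internal >= hi):
        raise ConfigurationError("internal knots must fall strictly inside the boundary knots")

    unscaled = SplineBasis(
        df=df,
        boundary_knots=(lo, hi),
        internal_knots=tuple(float(v) for v in internal),
        offset=tuple(0.0 for _ in range(df)),
        scale=tuple(1.0 for _ in range(df)),
    )
    at_lo = unscaled._raw(np.array(lo))
    at_hi = unscaled._raw(np.array(hi))
    span = at_hi - at_lo
    if np.any(np.abs(span) < 1e-12):
        raise ConfigurationError("degenerate basis: a basis function is flat across the range")
    return SplineBasis(
        df=df,
        boundary_knots=(lo, hi),
        internal_knots=tuple(float(v) for v in internal),
        offset=tuple(float(v) for v in at_lo),
        scale=tuple(float(v) for v in span),
    )


def evaluate_basis(basis: SplineBasis, day) -> np.ndarray:
    """Functional alias for :meth:`SplineBasis.evaluate`."""
    return basis.evaluate(day)
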