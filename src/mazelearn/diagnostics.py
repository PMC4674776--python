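"""MCMC convergence and mixing diagnostics.

Implements the original (non-split) Gelman-Rubin potential scale reduction
factor and an effective-sample-size estimator with Geyer's
initial-positive-sequence truncation of the autocorrelation sum.  A split
variant of the PSRF is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import PosteriorSamples


def gelman_rubin(chains, split: bool = False) -> float:
    """Potential scale reduction factor from >= 2 equal-length chains.

    PSRF = sqrt( (n-1)/n + B / (n W) ) with B the between-chain variance of
    the chain means (times n) and W the mean within-chain variance.  With
    ``split=True`` each chain is halved first (split-R-hat).

    Degenerate cases: W = 0 with B > 0 reports +inf; W = B = 0 reports 1.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length (2-D array)")
    if split:
        n2 = arr.shape[1] // 2
        arr = np.concatenate([arr[:, :n2], arr[:, n2 : 2 * n2]], axis=0)
    m, n = arr.shape
    if n < 4:
        raise ValueError("chains must each have length >= 4")
    means = arr.mean(axis=1)
    w = float(arr.var(axis=1, ddof=1).mean())
    b = float(n * means.var(ddof=1))
    if w == 0.0:
        return 1.0 if b == 0.0 else float("inf")
    return float(np.sqrt((n - 1) / n + b / (n * w)))


def _autocorrelations(x: np.ndarray) -> np.ndarray:
    """Autocorrelation function rho_0..rho_{n-1} via FFT (biased, 1/n)."""
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    if acov[0] <= 0:
        return np.zeros(n)
    return acov / acov[0]


def effective_sample_size(draws) -> float:
    """ESS = n / tau with tau from Geyer's initial positive sequence.

    Autocorrelations are accumulated in consecutive pairs
    Gamma_m = rho_{2m} + rho_{2m+1} and the sum stops before the first
    non-positive pair; tau = -1 + 2 * sum(Gamma_m).  A constant sequence
    reports ESS = n (zero-variance flag is the caller's concern);
    anticorrelated chains may legitimately report ESS > n.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("need a 1-D draw sequence of length >= 10")
    n = len(x)
    if np.ptp(x) == 0.0:
        return float(n)
    rho = _autocorrelations(x)
    tau = -1.0
    for m in range(n // 2):
        gamma = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < n else 0.0)
        if m > 0 and gamma <= 0.0:
            break
        tau += 2.0 * gamma
    tau = max(tau, 1.0 / n)  # antithetic chains: tau may reach 0
    return float(n / tau)


@dataclass
class DiagnosticsReport:
    """Per-parameter PSRF and ESS, with above-threshold flags."""

    table: pd.DataFrame  # parameter, psrf, psrf_rounded, ess_per_chain_mean, ess_combined, flagged
    threshold: float

    @property
    def converged(self) -> bool:
        return bool((self.table["psrf"] <= self.threshold).all())

    @property
    def max_psrf(self) -> float:
        return float(self.table["psrf"].max())

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "parameter"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary_metadata(self) -> dict:
        return {
            "max_psrf": self.max_psrf,
            "max_psrf_rounded": float(np.round(self.max_psrf, 1)),
            "converged": self.converged,
            "psrf_threshold": self.threshold,
            "flagged_parameters": self.flagged,
            "mean_ess_per_chain": float(self.table["ess_per_chain_mean"].mean()),
        }


def diagnose(
    samples: PosteriorSamples, threshold: float = 1.1, split: bool = False
) -> DiagnosticsReport:
    """Compute PSRF and ESS for every labelled parameter of a fit.

    Convergence is declared when all PSRFs are at or below ``threshold``
    (default 1.1); the report also carries PSRFs rounded to one decimal.
    ESS is reported per chain (mean across chains) and combined (sum).
    """
    if samples.n_chains < 2:
        raise ValueError("diagnostics require >= 2 chains")
    rows = []
    for j, label in enumerate(samples.labels):
        chains = samples.draws[:, :, j]
        psrf = gelman_rubin(chains, split=split)
        ess_per = [effective_sample_size(chain) for chain in chains]
        rows.append(
            {
                "parameter": label,
                "psrf": psrf,
                "psrf_rounded": float(np.round(psrf, 1)),
                "ess_per_chain_mean": float(np.mean(ess_per)),
                "ess_combined": float(np.sum(ess_per)),
                "flagged": bool(psrf > threshold),
            }
        )
    return DiagnosticsReport(table=pd.DataFrame(rows), threshold=threshold)
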