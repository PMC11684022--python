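"""Accuracy metrics and bootstrap confidence intervals for paired energies.

Conventions match the binding-energy benchmarking literature: MSE is the
*mean signed error* (not mean squared), SRC is Spearman's rank correlation,
and bootstrap confidence intervals are reported two ways — the normal-
approximation form X̄ ± z·σ/√n with σ the standard deviation of the
bootstrap statistic distribution (kept for fidelity with common usage, but
note that σ of the bootstrap distribution already scales like 1/√n, so the
extra √n shrinks the band), and the percentile interval, which is the one
with the expected frequentist coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

__all__ = ["MetricsReport", "BootstrapResult", "compute_metrics", "bootstrap_ci"]


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    mse: float  # mean signed error
    mae: float
    pearson_r: float  # nan when undefined (zero variance)
    spearman_src: float  # nan when undefined
    n: int


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float  # statistic on the original sample
    sigma: float  # std dev of the bootstrap statistic distribution
    iterations: int
    z: float
    n: int
    ci_low: float  # normal-approximation interval (estimate ± z σ/√n)
    ci_high: float
    percentile_low: float  # percentile interval at the same level
    percentile_high: float


def compute_metrics(pred, ref) -> MetricsReport:
    """Error and correlation metrics between computed and reference values."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or p.size < 1:
        raise ValueError("pred and ref must be equal-length 1-D vectors")
    diff = p - r
    rmse = float(np.sqrt(np.mean(diff**2)))
    mse = float(np.mean(diff))
    mae = float(np.mean(np.abs(diff)))
    if p.size < 2 or np.ptp(p) == 0 or np.ptp(r) == 0:
        pear = math.nan
        src = math.nan
    else:
        pear = float(sps.pearsonr(p, r).statistic)
        src = float(sps.spearmanr(p, r).statistic)
    return MetricsReport(
        rmse=rmse, mse=mse, mae=mae, pearson_r=pear, spearman_src=src, n=p.size
    )


def bootstrap_ci(
    values,
    statistic: Callable,
    B: int = 1000,
    seed: int = 0,
    z: float = 1.96,
) -> BootstrapResult:
    """Paired bootstrap of an arbitrary statistic.

    ``values`` is an (n,) vector or an (n, k) array whose rows are resampled
    as units (complexes stay paired with their references).  ``statistic``
    receives a resampled array of the same shape.  Resamples on which the
    statistic raises are redrawn, capped at 10·B attempts.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    estimate = float(statistic(arr))
    samples = np.empty(B)
    attempts = 0
    b = 0
    while b < B:
        if attempts >= 10 * B:
            raise RuntimeError("statistic kept failing on bootstrap resamples")
        idx = rng.integers(0, n, size=n)
        attempts += 1
        try:
            samples[b] = float(statistic(arr[idx]))
        except Exception:
            continue
        b += 1
    sigma = float(samples.std(ddof=1)) if B > 1 else 0.0
    half = z * sigma / math.sqrt(n)
    level = 2.0 * sps.norm.cdf(z) - 1.0
    lo_q = 100.0 * (1.0 - level) / 2.0
    plo, phi = np.percentile(samples, [lo_q, 100.0 - lo_q])
    return BootstrapResult(
        estimate=estimate,
        sigma=sigma,
        iterations=B,
        z=z,
        n=n,
        ci_low=estimate - half,
        ci_high=estimate + half,
        percentile_low=float(plo),
        percentile_high=float(phi),
    )
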