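"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q measures dispersion of the per-variant Wald ratios about the
pooled causal estimate, with inverse-variance weights w_j = bx_j^2 / sy_j^2
(first-order weights, exposure betas treated as fixed). I^2 re-expresses Q
as the percentage of dispersion beyond chance, floored at zero. A non-null
MR-Egger intercept signals directional pleiotropy; its test is a two-sided
normal test of intercept / se.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2, norm

from .exceptions import TwoSampleMRError
from .harmonize import HarmonizedSet

__all__ = ["HeterogeneityReport", "cochran_q", "egger_intercept_test"]


@dataclass(frozen=True)
class HeterogeneityReport:
    """Cochran's Q with its chi-square test and the derived I² percentage."""

    Q: float
    df: int
    p: float
    i2: float  # percentage in [0, 100]


def cochran_q(hset: HarmonizedSet, theta: float | None = None) -> HeterogeneityReport:
    """Cochran's Q of the Wald ratios about ``theta``.

    ``theta`` defaults to the fixed-effects IVW estimate, which is the
    weighted mean of the Wald ratios under these weights — Q then feeds the
    multiplicative overdispersion of random-effects IVW. Requires k >= 2.
    """
    k = hset.k
    if k < 2:
        raise TwoSampleMRError(f"heterogeneity undefined for k={k} (< 2 variants)")
    bx, _, by, sy = hset.arrays()
    ratios = [byj / bxj for bxj, byj in zip(bx, by)]
    weights = [bxj * bxj / (syj * syj) for bxj, syj in zip(bx, sy)]
    if theta is None:
        theta = sum(w * r for w, r in zip(weights, ratios)) / sum(weights)
    Q = sum(w * (r - theta) ** 2 for w, r in zip(weights, ratios))
    df = k - 1
    p = float(chi2.sf(Q, df))
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return HeterogeneityReport(Q=Q, df=df, p=p, i2=i2)


def egger_intercept_test(intercept) -> float:
    """Two-sided normal p-value for a non-zero MR-Egger intercept.

    Accepts anything with ``beta`` and ``se`` attributes (an
    :class:`~twosample_mr.estimators.MREstimate`) — a non-null intercept
    indicates directional pleiotropy, under which plain IVW is invalid.
    """
    if intercept.se <= 0:
        raise TwoSampleMRError("intercept standard error must be positive")
    return float(2.0 * norm.sf(abs(intercept.beta / intercept.se)))
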