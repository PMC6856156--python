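"""Instrument strength (F statistic, variance explained) and MR power.

The F statistic uses the joint k-instrument form

    F = (r² / k) / ((1 − r²) / (n − k − 1)),

with r² the variance of the (standardized) exposure explained by the
instruments and n the exposure-GWAS sample size; values above ~10 are the
conventional comfort zone against weak-instrument bias.

Power uses the approximation that a two-sample MR analysis has the
precision of the corresponding exposure-outcome regression run on
n_outcome · r² individuals, so the minimum detectable effect at two-sided
level alpha and a target power is

    b_min = (z_{1−alpha/2} + z_{power}) / sqrt(n_outcome · r²)

in outcome-SD units per unit of (standardized) exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm

from .exceptions import ValidationError
from .sumstats import GWASSummaryRecord

__all__ = [
    "StrengthReport",
    "approx_f_stat",
    "variance_explained",
    "min_detectable_effect",
    "build_strength_report",
]


@dataclass(frozen=True)
class StrengthReport:
    """Instrument strength and power for one exposure-outcome pair."""

    r2: float
    n_exposure: int
    k: int
    f_stat: float
    n_outcome: int | None = None
    alpha: float = 0.05
    power: float = 0.80
    min_detectable: float | None = None


def approx_f_stat(r2: float, n: int, k: int) -> float:
    """Joint F statistic of k instruments explaining r² in a GWAS of size n."""
    if not (0.0 <= r2 < 1.0):
        raise ValidationError(f"r2 {r2} outside [0, 1)")
    if k < 1:
        raise ValidationError(f"instrument count k={k} must be >= 1")
    if n <= k + 1:
        raise ValidationError(f"sample size n={n} must exceed k+1={k + 1}")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def variance_explained(records: Sequence[GWASSummaryRecord]) -> float:
    """Variance of a standardized exposure explained by independent variants.

    Uses the independent-instrument approximation
    r² = Σ_j 2·eaf_j·(1−eaf_j)·beta_j², which assumes the exposure betas are
    on a unit-variance scale and the instruments are uncorrelated (true
    after LD clumping). Empty input gives 0.
    """
    missing = [r.rsid for r in records if r.eaf is None]
    if missing:
        raise ValidationError(
            [f"{rsid}: eaf required to compute variance explained" for rsid in missing]
        )
    return sum(2.0 * r.eaf * (1.0 - r.eaf) * r.beta * r.beta for r in records)


def min_detectable_effect(
    n_outcome: int,
    r2: float,
    alpha: float = 0.05,
    power: float = 0.80,
) -> float:
    """Minimum detectable causal effect (outcome SD per unit exposure)."""
    if n_outcome <= 0 or r2 <= 0:
        raise ValidationError(
            f"n_outcome·r2 must be positive (n_outcome={n_outcome}, r2={r2})"
        )
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha {alpha} outside (0, 1)")
    if not (0.0 < power < 1.0):
        raise ValidationError(f"power {power} outside (0, 1)")
    z = float(norm.ppf(1.0 - alpha / 2.0) + norm.ppf(power))
    return z / math.sqrt(n_outcome * r2)


def build_strength_report(
    r2: float,
    n_exposure: int,
    k: int,
    n_outcome: int | None = None,
    alpha: float = 0.05,
    power: float = 0.80,
) -> StrengthReport:
    """Assemble F and (if an outcome size is given) the power column."""
    f = approx_f_stat(r2, n_exposure, k)
    mde = (
        min_detectable_effect(n_outcome, r2, alpha=alpha, power=power)
        if n_outcome
        else None
    )
    return StrengthReport(
        r2=r2,
        n_exposure=n_exposure,
        k=k,
        f_stat=f,
        n_outcome=n_outcome,
        alpha=alpha,
        power=power,
        min_detectable=mde,
    )
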