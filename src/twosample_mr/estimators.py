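"""Causal-effect estimators for two-sample MR on harmonized variants.

The estimator suite is the standard summary-data trio:

* **IVW** — inverse-variance-weighted meta-analysis of the per-variant Wald
  ratios, algebraically a weighted regression of outcome betas on exposure
  betas through the origin with weights 1/sy². The fixed-effects standard
  error assumes homogeneity; the random-effects version inflates it
  multiplicatively by max(1, sqrt(Q/(k-1))). Following the convention the
  source analyses use, the ``auto`` effects model picks random effects for
  4 or more instruments and fixed effects for 3 or fewer.
* **Weighted median** — the weight-interpolated median of the ordered Wald
  ratios; consistent when more than half the weight comes from valid
  instruments. Its standard error comes from a seeded parametric bootstrap.
* **MR-Egger** — the same weighted regression with a free intercept; the
  slope is the pleiotropy-adjusted effect under the InSIDE assumption and
  the intercept estimates the average directional pleiotropic effect.
  Standard errors carry the same multiplicative overdispersion, floored
  at 1.

Confidence intervals are normal-theory beta ± z₀.₉₇₅·se throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .diagnostics import cochran_q, egger_intercept_test
from .exceptions import (
    CollinearityError,
    EmptySetError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .harmonize import HarmonizedSet, HarmonizedVariant, orient_exposure_positive

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "egger",
    "estimate_all",
]

_Z975 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate (outcome SD per unit of the exposure scale)."""

    method: str
    k: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    notes: str = ""

    def rescaled(self, factor: float) -> "MREstimate":
        """Multiply beta/se/CI by ``factor`` (e.g. a per-100%-change rescale)."""
        return dc_replace(
            self,
            beta=self.beta * factor,
            se=self.se * factor,
            ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor,
        )


def _make_estimate(method: str, k: int, beta: float, se: float, notes: str = "") -> MREstimate:
    p = float(2.0 * norm.sf(abs(beta / se))) if se > 0 else float(beta == 0.0)
    return MREstimate(
        method=method,
        k=k,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z975 * se),
        ci_high=float(beta + _Z975 * se),
        pvalue=p,
        notes=notes,
    )


def wald_ratio(v: HarmonizedVariant) -> MREstimate:
    """Single-variant causal estimate: by/bx with first-order se = sy/|bx|."""
    if v.bx == 0.0:
        raise UndefinedRatioError(f"{v.rsid}: exposure beta is zero, ratio undefined")
    return _make_estimate("wald", 1, v.by / v.bx, v.sy / abs(v.bx), notes=v.rsid)


def ivw(hset: HarmonizedSet, effects_model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate across all variants.

    ``effects_model``: ``fixed``, ``random`` (multiplicative), or ``auto``
    (random iff k >= 4). With k = 1 this degenerates to the Wald ratio.
    """
    if effects_model not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    k = hset.k
    if k == 0:
        raise EmptySetError("IVW requires at least one variant")
    bx, _, by, sy = hset.arrays()
    sum_w = sum(b * b / (s * s) for b, s in zip(bx, sy))
    if sum_w == 0.0:
        raise UndefinedRatioError("all exposure betas are zero")
    beta = sum(bxj * byj / (syj * syj) for bxj, byj, syj in zip(bx, by, sy)) / sum_w
    se_fixed = math.sqrt(1.0 / sum_w)

    random = effects_model == "random" or (effects_model == "auto" and k >= 4)
    if random and k >= 2:
        het = cochran_q(hset, theta=beta)
        dispersion = max(1.0, math.sqrt(het.Q / (k - 1)))
        return _make_estimate("ivw_random", k, beta, se_fixed * dispersion)
    method = "ivw_random" if random else "ivw_fixed"
    return _make_estimate(method, k, beta, se_fixed)


def _wm_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    """Weighted median of Wald ratios: interpolate the weighted CDF at 1/2."""
    ratios = by / bx
    w = (bx * bx) / (sy * sy)
    w = w / w.sum()
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    wo = w[order]
    p = np.cumsum(wo) - wo / 2.0
    return float(np.interp(0.5, p, r))


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = 10_000,
    seed: int | None = 0,
) -> MREstimate:
    """Weighted-median estimate with a seeded parametric-bootstrap SE.

    Each bootstrap replicate resamples bx_j ~ N(bx_j, sx_j) and
    by_j ~ N(by_j, sy_j) and recomputes the weighted median; the SE is the
    standard deviation across replicates. The point estimate itself is
    deterministic. Requires k >= 3.
    """
    if hset.k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires k >= 3, got k={hset.k}"
        )
    bx, sx, by, sy = (np.asarray(a, dtype=float) for a in hset.arrays())
    point = _wm_point(bx, by, sy)

    rng = np.random.default_rng(seed)
    k = hset.k
    bxs = bx + rng.standard_normal((n_boot, k)) * sx
    bys = by + rng.standard_normal((n_boot, k)) * sy
    # Guard the vanishingly rare exact-zero resample of an exposure beta.
    bxs[bxs == 0.0] = np.finfo(float).tiny
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = _wm_point(bxs[i], bys[i], sy)
    se = float(np.std(reps, ddof=1))
    return _make_estimate("weighted_median", k, point, se)


def egger(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: returns (slope, intercept) estimates.

    Weighted least squares of by on bx with a free intercept and weights
    1/sy², after canonically orienting all exposure betas positive (the
    Egger fit is not invariant to allele orientation). Standard errors are
    scaled by max(1, sqrt(residual heterogeneity)) — multiplicative
    overdispersion with the dispersion floored at 1. Requires k >= 3.
    """
    if hset.k < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires k >= 3, got k={hset.k}"
        )
    oriented = orient_exposure_positive(hset)
    k = oriented.k
    if k < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires k >= 3 usable variants, got k={k}"
        )
    bx, _, by, sy = (np.asarray(a, dtype=float) for a in oriented.arrays())
    w = 1.0 / (sy * sy)
    sw = w.sum()
    swx = (w * bx).sum()
    swy = (w * by).sum()
    swxx = (w * bx * bx).sum()
    swxy = (w * bx * by).sum()
    delta = sw * swxx - swx * swx
    if delta <= 0 or delta < 1e-12 * sw * swxx:
        raise CollinearityError("no variation in exposure betas; Egger fit singular")
    slope = (sw * swxy - swx * swy) / delta
    intercept = (swy - slope * swx) / sw

    resid = by - intercept - slope * bx
    rss_w = float((w * resid * resid).sum())
    dispersion = max(1.0, math.sqrt(rss_w / (k - 2)))
    se_slope = math.sqrt(sw / delta) * dispersion
    se_intercept = math.sqrt(swxx / delta) * dispersion
    return (
        _make_estimate("egger_slope", k, slope, se_slope),
        _make_estimate("egger_intercept", k, intercept, se_intercept),
    )


#: Minimum instrument counts at which each method is applicable.
METHOD_MIN_K = {"ivw": 1, "weighted_median": 3, "egger": 3}


def estimate_all(
    sets: Mapping[str, HarmonizedSet] | HarmonizedSet,
    methods: Sequence[str] = ("ivw", "weighted_median", "egger"),
    effects_model: str = "auto",
    n_boot: int = 10_000,
    seed: int = 0,
    rescale: float = 1.0,
    extra_columns: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Run the estimator suite over one or more instrument sets.

    Returns one row per (instrument set x applicable method), with
    heterogeneity diagnostics (Q about the fixed-effects IVW estimate, its
    p-value and I²) attached where k >= 2 and the Egger intercept test
    attached to Egger rows. Methods requiring k >= 3 are silently skipped
    for smaller sets, mirroring the sensitivity-table convention of
    reporting only IVW for 2-variant panels. ``rescale`` multiplies
    betas/SEs/CIs (e.g. a per-100%-change-in-exposure rescaling);
    deterministic given ``seed``.
    """
    if isinstance(sets, HarmonizedSet):
        sets = {"all": sets}
    unknown = [m for m in methods if m not in METHOD_MIN_K]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")

    rows: list[dict] = []
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(len(sets))
    for (label, hset), child in zip(sets.items(), child_seeds):
        k = hset.k
        het = cochran_q(hset) if k >= 2 else None
        common = {
            "set_label": label,
            "Q": het.Q if het else float("nan"),
            "Q_df": het.df if het else 0,
            "Q_p": het.p if het else float("nan"),
            "i2": het.i2 if het else float("nan"),
        }
        common.update(extra_columns or {})

        def emit(est: MREstimate, **extras) -> None:
            est = est.rescaled(rescale)
            rows.append(
                {
                    **common,
                    "method": est.method,
                    "k": est.k,
                    "beta": est.beta,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pvalue": est.pvalue,
                    **extras,
                }
            )

        if "ivw" in methods and k >= 1:
            emit(ivw(hset, effects_model=effects_model))
        if "weighted_median" in methods and k >= METHOD_MIN_K["weighted_median"]:
            wm_seed = int(child.generate_state(1)[0] % (2**31))
            emit(weighted_median(hset, n_boot=n_boot, seed=wm_seed))
        if "egger" in methods and k >= METHOD_MIN_K["egger"]:
            # The intercept lives on the outcome scale regardless of any
            # exposure-scale rescaling, so it is reported unrescaled.
            slope, intercept = egger(hset)
            emit(
                slope,
                egger_intercept=intercept.beta,
                egger_intercept_se=intercept.se,
                egger_intercept_p=egger_intercept_test(intercept),
            )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        lead = ["set_label", "method", "k", "beta", "se", "ci_low", "ci_high", "pvalue"]
        frame = frame[[*lead, *[c for c in frame.columns if c not in lead]]]
    return frame
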