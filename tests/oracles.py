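"""Independent brute-force oracles the estimators are checked against.

Each oracle takes a different computational route from the implementation:
matrix least squares on the weighted design instead of summation formulas,
and direct breakpoint enumeration instead of vectorized interpolation.
"""

import numpy as np


def ivw_origin_wls(bx, by, sy):
    """Weighted regression through the origin solved via lstsq on the
    whitened design; returns (beta, fixed-effects se)."""
    bx, by, sy = (np.asarray(a, float) for a in (bx, by, sy))
    x = (bx / sy)[:, None]
    y = by / sy
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    se = float(np.sqrt(np.linalg.inv(x.T @ x)[0, 0]))
    return float(beta[0]), se


def egger_wls(bx, by, sy):
    """Weighted regression with intercept via the whitened normal equations;
    returns (slope, intercept, se_slope, se_intercept) at unit scale."""
    bx, by, sy = (np.asarray(a, float) for a in (bx, by, sy))
    X = np.column_stack([np.ones_like(bx), bx]) / sy[:, None]
    y = by / sy
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ y
    ses = np.sqrt(np.diag(xtx_inv))
    return float(coef[1]), float(coef[0]), float(ses[1]), float(ses[0])


def weighted_median_bruteforce(bx, by, sy):
    """Weighted median of Wald ratios by explicit breakpoint walking."""
    bx, by, sy = (np.asarray(a, float) for a in (bx, by, sy))
    ratios = list(by / bx)
    weights = list(bx**2 / sy**2)
    total = sum(weights)
    pairs = sorted(zip(ratios, weights))
    cum = 0.0
    points = []
    for r, w in pairs:
        points.append((cum + w / 2.0, r))  # midpoint cumulative weight
        cum += w
    points = [(p / total, r) for p, r in points]
    if 0.5 <= points[0][0]:
        return points[0][1]
    if 0.5 >= points[-1][0]:
        return points[-1][1]
    for (p0, r0), (p1, r1) in zip(points, points[1:]):
        if p0 <= 0.5 <= p1:
            return r0 + (r1 - r0) * (0.5 - p0) / (p1 - p0)
    raise AssertionError("unreachable")


def random_harmonized_arrays(rng, k):
    """A random well-conditioned (bx, sx, by, sy) quadruple."""
    bx = rng.uniform(0.03, 0.3, k) * rng.choice([-1.0, 1.0], k)
    sx = rng.uniform(0.002, 0.02, k)
    by = rng.normal(0.2 * bx, 0.01)
    sy = rng.uniform(0.002, 0.02, k)
    return bx, sx, by, sy
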