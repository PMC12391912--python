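"""Independent hand-coded oracles used by the test suite.

These re-derive expected values along routes that share no code with the
package: the jackknife-richness oracle uses the closed-form coefficient table
of the generalized jackknife (frozen rational expressions in ``n``), while the
package solves the bias-cancellation linear system in exact arithmetic.
"""

import math

import numpy as np
from scipy import stats


def jackknife_table_coeffs(n, k):
    """Closed-form frequency-count coefficients of the order-k jackknife."""
    if k == 1:
        return [(n - 1) / n]
    if k == 2:
        return [(2 * n - 3) / n, -((n - 2) ** 2) / (n * (n - 1))]
    if k == 3:
        return [
            3 * (n - 2) / n,
            -(3 * n**2 - 15 * n + 19) / (n * (n - 1)),
            (n - 3) ** 3 / (n * (n - 1) * (n - 2)),
        ]
    if k == 4:
        return [
            2 * (2 * n - 5) / n,
            -(6 * n**2 - 36 * n + 55) / (n * (n - 1)),
            (2 * n - 7) * (2 * n**2 - 14 * n + 25) / (n * (n - 1) * (n - 2)),
            -((n - 4) ** 4) / (n * (n - 1) * (n - 2) * (n - 3)),
        ]
    if k == 5:
        return [
            5 * (n - 3) / n,
            -5 * (2 * n**2 - 14 * n + 25) / (n * (n - 1)),
            5 * (n - 4) * (2 * n**2 - 16 * n + 33) / (n * (n - 1) * (n - 2)),
            -(5 * n**4 - 90 * n**3 + 610 * n**2 - 1845 * n + 2101)
            / (n * (n - 1) * (n - 2) * (n - 3)),
            (n - 5) ** 5 / (n * (n - 1) * (n - 2) * (n - 3) * (n - 4)),
        ]
    raise ValueError("oracle supports orders 1..5")


def jackknife_oracle(counts, max_order=5, alpha=0.05):
    """Burnham-Overton estimate + order via the closed-form table.

    Independent implementation of the estimator cascade: order 0 iff no
    singletons; otherwise raise the order from 1 while the increment to the
    next order is significantly positive under the B&O variance.
    """
    x = np.asarray(counts)
    x = x[x > 0].astype(int)
    n = int(x.sum())
    s_obs = len(x)
    f = np.bincount(x, minlength=max(max_order + 2, x.max() + 1))
    kmax = min(max_order, n - 1)

    def estimate(k):
        if k == 0:
            return float(s_obs)
        cs = jackknife_table_coeffs(n, k)
        return s_obs + sum(cs[i - 1] * f[i] for i in range(1, k + 1))

    def coeff(k, i):
        if k == 0 or i > k:
            return 0.0
        return jackknife_table_coeffs(n, k)[i - 1]

    if f[1] == 0 or kmax < 1:
        return float(s_obs), 0
    sel = min(1, kmax)
    for k in range(1, kmax):
        d = estimate(k + 1) - estimate(k)
        if d <= 1e-12:
            break
        ssq = sum((coeff(k + 1, i) - coeff(k, i)) ** 2 * f[i] for i in range(1, k + 2))
        var = (n / (n - 1.0)) * (ssq - d**2 / n) if n > 1 else 0.0
        if var <= 1e-9 * max(ssq, 1e-300):
            break
        if 2.0 * stats.norm.sf(abs(d / math.sqrt(var))) >= alpha:
            break
        sel = k + 1
    return float(max(estimate(sel), s_obs)), sel


def hill_oracle(p, q):
    """Direct evaluation of the Hill-number formulas, no shared helpers."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    if q == 1:
        return math.exp(-sum(pi * math.log(pi) for pi in p))
    if q == 0:
        return float(len(p))
    return float(sum(pi**q for pi in p) ** (1.0 / (1.0 - q)))


def ok_system_oracle(gamma_fn, obs_points, target):
    """Ordinary-kriging weights via an explicitly assembled dense solve."""
    pts = np.asarray(obs_points, dtype=float)
    n = len(pts)
    a = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            if i != j:
                a[i, j] = gamma_fn(np.linalg.norm(pts[i] - pts[j]))
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        h = np.linalg.norm(pts[i] - np.asarray(target, dtype=float))
        b[i] = gamma_fn(h) if h > 0 else 0.0
    b[n] = 1.0
    sol = np.linalg.solve(a, b)
    return sol[:n]


def nb_pmf_series_oracle(y, mu, sigma):
    """NB pmf via the gamma-function form evaluated with logs directly."""
    r = 1.0 / sigma
    p = r / (r + mu)
    return math.exp(
        math.lgamma(y + r) - math.lgamma(r) - math.lgamma(y + 1)
        + r * math.log(p) + y * math.log(1 - p)
    )
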