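"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they validate: the QP oracle
enumerates active sets and solves small KKT systems directly; the Wilcoxon
oracle enumerates all 2^n sign assignments explicitly.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import norm, rankdata


def active_set_qp_oracle(R, lo, hi, tau, f_max):
    """Minimize sum((f_i/f_max_i)^2) s.t. R f = tau, lo <= f <= hi.

    Enumerates every assignment of muscles to {lower bound, upper bound,
    free}, solves the equality-constrained quadratic for the free block via
    its KKT system, and returns (f, cost) of the best feasible candidate,
    or (None, None) if no assignment is feasible.
    """
    R = np.asarray(R, float)
    m = R.shape[1]
    w = 1.0 / np.asarray(f_max, float) ** 2  # cost = sum w f^2
    best_f, best_cost = None, np.inf
    tol = 1e-8 * max(1.0, np.abs(tau).max())
    for assign in itertools.product((0, 1, 2), repeat=m):
        f = np.empty(m)
        clamped = []
        free = []
        for i, a in enumerate(assign):
            if a == 0:
                f[i] = lo[i]
                clamped.append(i)
            elif a == 1:
                f[i] = hi[i]
                clamped.append(i)
            else:
                free.append(i)
        b = tau - (R[:, clamped] @ f[clamped] if clamped else 0.0)
        if free:
            A = R[:, free]
            Winv = 1.0 / w[free]
            M = (A * Winv) @ A.T
            try:
                nu = np.linalg.lstsq(M, b, rcond=None)[0]
            except np.linalg.LinAlgError:
                continue
            f_free = Winv * (A.T @ nu)
            f[free] = f_free
        if np.max(np.abs(R @ f - tau)) > tol:
            continue
        if np.any(f < lo - 1e-9) or np.any(f > hi + 1e-9):
            continue
        cost = float(np.sum(w * np.clip(f, lo, hi) ** 2))
        if cost < best_cost:
            best_cost, best_f = cost, np.clip(f, lo, hi)
    if best_f is None:
        return None, None
    return best_f, best_cost


def random_distribution_instance(rng, m=None, zero_lower=False, feasible=True):
    """Random bounded instance with a demand drawn inside (or far outside)
    the achievable set."""
    if m is None:
        m = int(rng.integers(2, 5))
    while True:
        R = rng.uniform(-20, 20, (2, m))
        if not np.any(np.linalg.norm(R, axis=0) < 1e-6):
            break
    lo = np.zeros(m) if zero_lower else rng.uniform(0, 5, m)
    hi = lo + rng.uniform(10, 150, m)
    if feasible:
        tau = R @ rng.uniform(lo, hi)
    else:
        span = np.abs(R) @ hi
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        tau = direction * (np.linalg.norm(span) * 10 + 100)
    return R, lo, hi, tau


def wilcoxon_exact_enumeration(d):
    """Two-sided exact signed-rank p by explicit 2^n enumeration.

    Zero differences are dropped; |d| receive mid-ranks; the statistic is
    W = min(W+, W-) and p = 2 P(W+ <= W) under the sign-flip null.
    """
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if wp <= w_obs + 1e-9:
            count += 1
    return w_obs, min(1.0, 2.0 * count / 2**n)


def wilcoxon_asymptotic_closed_form(w, n):
    """No-ties normal-approximation p: z = (W - n(n+1)/4)/sqrt(n(n+1)(2n+1)/24)."""
    mean = n * (n + 1) / 4.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w - mean) / sd
    return 2.0 * norm.cdf(z)
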