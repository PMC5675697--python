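"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity from its textbook definition (enumeration,
closed form, explicit product/summation) without touching the implementation
paths it is used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """U and two-sided exact p by full enumeration of group assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = np.array([
        ranks[list(idx)].sum() - na * (na + 1) / 2
        for idx in itertools.combinations(range(n), na)
    ])
    lo = (us <= u_obs + 1e-9).mean()
    hi = (us >= u_obs - 1e-9).mean()
    return float(u_obs), float(min(1.0, 2 * min(lo, hi)))


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for i in range(n - 1, -1, -1):
        prev = min(prev, p[order[i]] * n / (i + 1))
        q[order[i]] = prev
    return q


def hypergeom_tail(hits: int, universe: int, annotated: int, set_size: int) -> float:
    """P(X >= hits) by explicit summation of the hypergeometric pmf."""
    total = 0.0
    denom = math.comb(universe, set_size)
    for k in range(hits, min(annotated, set_size) + 1):
        total += math.comb(annotated, k) * math.comb(universe - annotated, set_size - k) / denom
    return total


def spearman_permutation_p(x, y) -> float:
    """Two-sided exact permutation p for Spearman rho (recomputed per permutation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho_obs = abs(stats.spearmanr(x, y).statistic)
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        r = abs(stats.spearmanr(x, np.asarray(perm)).statistic)
        if r >= rho_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def regression_slope_test(x, y) -> tuple[float, float]:
    """Slope t-test of simple linear regression from the closed-form algebra."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    resid = y - ybar - slope * (x - xbar)
    se = math.sqrt((resid**2).sum() / (n - 2) / sxx)
    t = slope / se
    return slope, 2 * stats.t.sf(abs(t), n - 2)


def km_product_limit(times, events):
    """Hand product-limit estimator: (event times, S at those times)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    s = 1.0
    out_t, out_s = [], []
    for t in np.unique(times[events == 1]):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_permutation_p(times, events, labels_low, chi2_fn) -> float:
    """Exact permutation p of the log-rank statistic over all label assignments.

    ``chi2_fn(t_lo, e_lo, t_hi, e_hi) -> chi2`` computes the statistic; all
    C(n, n_low) assignments with the observed stratum sizes are enumerated.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels_low = np.asarray(labels_low, dtype=bool)
    n = times.size
    n_low = int(labels_low.sum())
    obs = chi2_fn(times[labels_low], events[labels_low], times[~labels_low], events[~labels_low])
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n_low):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        c = chi2_fn(times[mask], events[mask], times[~mask], events[~mask])
        if c >= obs - 1e-9:
            count += 1
        total += 1
    return count / total


def moderated_t_direct(y_a, y_b, s2_prior, d0):
    """Moderated two-group t from the posterior-variance formula, plain loops."""
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    na, nb = y_a.size, y_b.size
    fc = y_b.mean() - y_a.mean()
    rss = ((y_a - y_a.mean()) ** 2).sum() + ((y_b - y_b.mean()) ** 2).sum()
    dg = na + nb - 2
    s2 = rss / dg
    if math.isinf(d0):
        s2_post = s2_prior
        df = math.inf
    else:
        s2_post = (d0 * s2_prior + dg * s2) / (d0 + dg)
        df = d0 + dg
    t = fc / math.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    p = 2 * (stats.norm.sf(abs(t)) if math.isinf(df) else stats.t.sf(abs(t), df))
    return t, p
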