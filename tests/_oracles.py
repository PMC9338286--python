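"""Independent brute-force oracles used to validate the package's numerics.

These deliberately avoid the implementation paths they check: the probit
oracle is a derivative-free multi-start search on a likelihood written with
scipy.stats, and the Wilcoxon oracle enumerates all 2^n sign assignments.
"""

from itertools import product

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm, rankdata


def probit_nll(beta, x1, x2, y):
    t = beta[0] + beta[1] * x1 + beta[2] * x2
    return -np.sum(y * norm.logcdf(t) + (1 - y) * norm.logcdf(-t))


def probit_oracle_loglik(x1, x2, y, n_starts=20, seed=0):
    """Best log-likelihood found by Nelder-Mead from many random starts."""
    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3), np.array([0.0, 1.0, 0.0])]
    while len(starts) < n_starts:
        starts.append(rng.normal(scale=1.5, size=3))
    for b0 in starts:
        res = minimize(
            probit_nll,
            b0,
            args=(x1, x2, y),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        best = min(best, res.fun)
    return -best


def wilcoxon_enumeration_p(diffs):
    """Exact two-tailed signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = np.array(
        [sum(r for r, m in zip(ranks, mask) if m) for mask in product((0, 1), repeat=n)]
    )
    p_le = np.mean(sums <= w_obs + 1e-9)
    p_ge = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))
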