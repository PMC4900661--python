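"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most direct method
available (exhaustive enumeration, naive O(n^2) sums, closed forms) and
stay independent of the package implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_ward(X: np.ndarray):
    """Exhaustive minimum-SSE-increase agglomeration on Euclidean points.

    At every step evaluates the total within-cluster SSE increase of every
    candidate pair merge and takes the smallest.  Returns the merge
    history as (member_set_a, member_set_b, delta_sse) triples.
    """

    def sse(idx):
        pts = X[list(idx)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(X))]
    history = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            merged = clusters[a] | clusters[b]
            delta = sse(merged) - sse(clusters[a]) - sse(clusters[b])
            if best is None or delta < best[0]:
                best = (delta, a, b)
        delta, a, b = best
        history.append((clusters[a], clusters[b], delta))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return history


def naive_hpd(x, mass: float):
    """Shortest interval by explicit scan over every contiguous window."""
    xs = np.sort(np.asarray(x, float))
    n = xs.size
    m = int(np.ceil(mass * n))
    best = (np.inf, None, None)
    for i in range(n - m + 1):
        width = xs[i + m - 1] - xs[i]
        if width < best[0]:
            best = (width, xs[i], xs[i + m - 1])
    return best[1], best[2]


def naive_ess(x):
    """ESS via direct O(n^2)-style autocovariance sums and Geyer pairs."""
    x = np.asarray(x, float)
    n = x.size
    xc = x - x.mean()
    acov = np.array([np.sum(xc[: n - k] * xc[k:]) / n for k in range(n)])
    rho = acov / acov[0]
    tau = -1.0
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma <= 0:
            break
        tau += 2 * gamma
        m += 1
    return min(n / max(tau, 1.0), n)


def conjugate_sigma2_posterior(y: np.ndarray, X: np.ndarray, prior_df: int, prior_scale: float):
    """Closed-form marginal posterior of the residual variance for the
    fixed-effects Gaussian model y = X beta + e with a flat beta prior and
    a scaled inverse-chi-square (1-d inverse-Wishart) prior on sigma2.

    Returns the scipy ``invgamma`` shape and scale: sigma2 | y ~
    InvGamma((N - p + n0)/2, (RSS + s0)/2).
    """
    n, p = X.shape
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta_hat) ** 2).sum())
    shape = (n - p + prior_df) / 2.0
    scale = (rss + prior_scale) / 2.0
    return shape, scale
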