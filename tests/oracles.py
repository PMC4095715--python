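"""Independent oracles used by the test suite.

Each oracle computes the same quantity as the implementation by a
different route (dynamic programming over urn states, Monte Carlo urn
draws, direct normal equations) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def urn_exact_pmf(n: int, m1: int, N: int, w1: float, w2: float = 1.0) -> np.ndarray:
    """Exact weighted-urn pmf by forward dynamic programming.

    Items are drawn one at a time without replacement; at step i with x
    pathway items already drawn, the next draw is a pathway item with
    probability w1*(m1-x) / (w1*(m1-x) + w2*(m2-(i-x))). The state after
    i draws is fully described by x, so the forward pass is exact.
    """
    m2 = N - m1
    probs = {0: 1.0}
    for i in range(n):
        nxt: dict[int, float] = {}
        for x, p in probs.items():
            reds = m1 - x
            others = m2 - (i - x)
            total = w1 * reds + w2 * others
            if total <= 0:
                continue
            if reds > 0:
                nxt[x + 1] = nxt.get(x + 1, 0.0) + p * w1 * reds / total
            if others > 0:
                nxt[x] = nxt.get(x, 0.0) + p * w2 * others / total
        probs = nxt
    out = np.zeros(min(n, m1) + 1)
    for x, p in probs.items():
        out[x] += p
    return out


def urn_upper_tail(g: int, n: int, m1: int, N: int, w1: float, w2: float = 1.0) -> float:
    """P(X >= g) from the exact urn dynamic program."""
    pmf = urn_exact_pmf(n, m1, N, w1, w2)
    return float(pmf[g:].sum())


def urn_monte_carlo(
    n: int, m1: int, N: int, w1: float, w2: float, draws: int, seed: int
) -> np.ndarray:
    """Monte Carlo urn estimate of the pmf (vectorized over replicates)."""
    rng = np.random.default_rng(seed)
    m2 = N - m1
    x = np.zeros(draws, dtype=int)
    for i in range(n):
        reds = m1 - x
        others = m2 - (i - x)
        p_red = w1 * reds / (w1 * reds + w2 * others)
        x += (rng.random(draws) < p_red).astype(int)
    return np.bincount(x, minlength=min(n, m1) + 1).astype(float) / draws


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct normal-equations least squares solve."""
    return np.linalg.solve(x.T @ x, x.T @ y)


def pearson_covariance_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r straight from the covariance formula."""
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
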