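"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive each quantity from first principles
(enumeration, double loops) and share no code with the package.
"""

import itertools

import numpy as np
from scipy import stats as sps


def enum_mw_p(x, y, alternative):
    """Mann-Whitney p by literal enumeration of all group assignments."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(n), n1)]
    )
    eps = 1e-9
    p_low = np.mean(sums <= obs + eps)
    p_high = np.mean(sums >= obs - eps)
    if alternative == "less":
        return p_low
    if alternative == "greater":
        return p_high
    return min(1.0, 2.0 * min(p_low, p_high))


def bh_oracle(p):
    """Textbook BH step-up: adj_(i) = min_{j >= i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sp = p[order]
    adj_sorted = [
        min(1.0, min(m * sp[j] / (j + 1) for j in range(i, m))) for i in range(m)
    ]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def enum_hypergeom_tail(M, K, n, k):
    """P(overlap >= k) by enumerating every n-subset of an M-universe."""
    success_mask = (1 << K) - 1
    hits = total = 0
    for draw in itertools.combinations(range(M), n):
        mask = 0
        for d in draw:
            mask |= 1 << d
        total += 1
        if bin(mask & success_mask).count("1") >= k:
            hits += 1
    return hits / total
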