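"""Independent brute-force oracles used to validate the implementation."""

import math

import numpy as np


def auc_bruteforce(scores, labels, positive="DLB"):
    """Pairwise Mann-Whitney AUC; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def fisher_bruteforce(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x)
            * math.comb(r2, c1 - x)
            / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(
        prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7)
    )


def binomial_tail(k, n, p):
    """P(X >= k) by direct summation."""
    return sum(
        math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(k, n + 1)
    )


def segment_starts(duration, length, step):
    """Enumerate admissible window start times on a fine grid."""
    starts = []
    t = 0.0
    while t + length <= duration + 1e-9:
        starts.append(t)
        t += step
    return starts


def exhaustive_mask_search(fitness_fn, n_features):
    """Best mask over all non-empty subsets (small n_features only)."""
    best_mask, best_fit = None, -np.inf
    for code in range(1, 2**n_features):
        mask = np.array(
            [(code >> i) & 1 for i in range(n_features)], dtype=bool
        )
        f = fitness_fn(mask)
        if f > best_fit:
            best_fit, best_mask = f, mask
    return best_mask, best_fit
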