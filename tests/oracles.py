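"""Independent brute-force oracles used to cross-check the statistics."""

from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration of the hypergeometric support.

    Sums the point probabilities of every table sharing the observed margins
    whose probability does not exceed the observed one (with a small relative
    tolerance for ties at machine precision).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        p_x = comb(r1, x) * comb(r2, c1 - x) / denom
        if p_x <= p_obs * (1 + 1e-7):
            total += p_x
    return min(total, 1.0)


def bh_stepup_oracle(p_values):
    """Naive O(n^2) Benjamini-Hochberg step-up from the definition.

    For the i-th smallest p-value, the adjusted value is
    min over j >= i of p_(j) * n / j, clipped at 1.  The suffix minimum is
    recomputed from scratch for every i (no step-up recursion), so this stays
    an independent restatement of the definition.
    """
    import numpy as np

    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.empty(n)
    for rank_i in range(n):
        adjusted[order[rank_i]] = min(scaled[rank_i:].min(), 1.0)
    return adjusted.tolist()
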