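"""Independent brute-force oracles used only by the tests.

All computations here deliberately avoid the package's own code paths:
exact integer combinatorics for the Fisher tests and plain Python loops
for window aggregation.
"""

from __future__ import annotations

from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by enumerating every table with the same
    margins and summing those no more probable than the observed one.

    Works in exact integer weights (the common denominator C(n, c1)
    cancels), so tie comparison is exact.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    weights = [comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    return sum(w for w in weights if w <= w_obs) / comb(n, c1)


def hypergeom_upper_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n) by enumeration."""
    hi = min(K, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, hi + 1)) / comb(N, n)


def window_sums_oracle(records, samples, chrom, start, end):
    """Pooled (meth, total) per sample over [start, end) by a naive scan.

    ``records`` is the wide per-cytosine DataFrame; returns
    {sample: (meth, total)}.
    """
    out = {s: [0, 0] for s in samples}
    for _, row in records.iterrows():
        if row["chrom"] != chrom or not (start <= row["pos"] < end):
            continue
        for s in samples:
            m, u = int(row[f"meth_{s}"]), int(row[f"unmeth_{s}"])
            out[s][0] += m
            out[s][1] += m + u
    return {s: tuple(v) for s, v in out.items()}
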