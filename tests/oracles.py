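"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact integer/rational
arithmetic for Fisher's test, per-position string slicing for motif counts,
and full enumeration for the rank tests.
"""

from itertools import combinations, product
from math import comb


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration in exact
    integer arithmetic (relative tie tolerance 1e-7, as in the convention)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = [comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    M = 10**7
    total = sum(x for x in nums if x * M <= obs * (M + 1))
    return total / comb(n, c1)


def motif_bin_counts_oracle(sequence: str, motif: str, bin_size: int) -> list[int]:
    """Motif counts per bin by checking every start position with a slice."""
    seq = sequence.upper()
    motif = motif.upper()
    n_bins = -(-len(seq) // bin_size)
    counts = [0] * n_bins
    for i in range(len(seq) - len(motif) + 1):
        if seq[i : i + len(motif)] == motif:
            counts[i // bin_size] += 1
    return counts


def signed_rank_oracle_all_positive(n: int) -> float:
    """Exact two-sided p of the signed-rank test when every one of n
    differences is positive: enumerate all 2^n sign patterns of the ranks."""
    ranks = list(range(1, n + 1))
    w_obs = sum(ranks)  # all-positive pattern attains the maximum
    total = 0
    extreme = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        # two-sided: patterns at least as extreme in either direction
        if w >= w_obs or w <= (sum(ranks) - w_obs):
            extreme += 1
    return extreme / total


def mannwhitney_oracle(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all rank splits
    (assumes no ties across the pooled sample)."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires untied data"
    n, m = len(x), len(y)
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank_of[v] for v in x) - n * (n + 1) / 2
    us = []
    for idx in combinations(range(1, n + m + 1), n):
        us.append(sum(idx) - n * (n + 1) / 2)
    total = len(us)
    le = sum(u <= u_obs for u in us) / total
    ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(le, ge))
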