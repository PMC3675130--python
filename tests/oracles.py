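"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive (explicit loops, exact rational arithmetic
where possible) and share no code with the package internals.
"""

from fractions import Fraction
from math import factorial


def hwe_exact_oracle(n0: int, n1: int, n2: int) -> float:
    """Exact two-sided HWE p by full rational enumeration (totals <= ~60)."""
    n = n0 + n1 + n2
    na = n1 + 2 * n2
    rare = min(na, 2 * n - na)
    if rare == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        probs[h] = Fraction(
            factorial(n) * 2 ** h,
            factorial(hom_rare) * factorial(h) * factorial(hom_common),
        )
    total = sum(probs.values())
    obs = probs[n1]
    return float(sum(v for v in probs.values() if v <= obs) / total)


def es_step_oracle(stats, member_idx, weight=1.0):
    """Enrichment score by explicit walk down the ranked list.

    ``stats`` in gene order (assumed symbol-sorted); ranking is by
    statistic descending with the stable (symbol) tie-break.
    """
    n = len(stats)
    member = set(member_idx)
    order = sorted(range(n), key=lambda i: -stats[i])
    nh = len(member)
    nr = sum(abs(stats[i]) ** weight for i in member)
    run, best = 0.0, float("-inf")
    for i in order:
        if i in member:
            run += abs(stats[i]) ** weight / nr
        else:
            run -= 1.0 / (n - nh)
        best = max(best, run)
    return best


def rtp_oracle(pvals, K):
    """Plain product of the K smallest p-values."""
    prod = 1.0
    for p in sorted(pvals)[:K]:
        prod *= p
    return prod


def artp_oracle(gene_p, k_set):
    """Adjusted ARTP p by recomputing every rank with explicit loops.

    ``gene_p`` is a (L, B+1) nested list/array; column 0 observed.
    """
    L = len(gene_p)
    C = len(gene_p[0])
    cols = [[gene_p[i][b] for i in range(L)] for b in range(C)]
    ks = sorted(k for k in set(k_set) if 1 <= k <= L)
    W = [[rtp_oracle(cols[b], K) for b in range(C)] for K in ks]
    t = []
    for b in range(C):
        s_min = 1.0
        for ki in range(len(ks)):
            cnt = sum(1 for b2 in range(C) if b2 != b and W[ki][b2] <= W[ki][b])
            s_min = min(s_min, (1 + cnt) / C)
        t.append(s_min)
    return (1 + sum(1 for b in range(1, C) if t[b] <= t[0])) / C


def best_snp_oracle(pvals_by_snp, snp_lists, flagged=None):
    """Per-gene argmin-p by exhaustive scan; returns chosen SNP indices."""
    flagged = flagged or set()
    chosen = []
    for snps in snp_lists:
        best, best_p = -1, float("inf")
        for j in snps:  # snps pre-sorted by (position, id)
            if j in flagged:
                continue
            if pvals_by_snp[j] < best_p:
                best, best_p = j, pvals_by_snp[j]
        chosen.append(best)
    return chosen


def fdr_oracle(nes_obs, nes_perm):
    """Ratio-of-tail-fractions FDR by explicit double loop (positive side)."""
    flat = [v for row in nes_perm for v in row]
    out = []
    for star in nes_obs:
        if star <= 0:
            out.append(1.0)
            continue
        num = sum(1 for v in flat if v >= star) / len(flat)
        den = sum(1 for v in nes_obs if v >= star) / len(nes_obs)
        out.append(min(1.0, num / den) if den > 0 else 1.0)
    return out
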