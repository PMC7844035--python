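"""Independent brute-force oracles used only by the tests.

Each function is a direct scalar transcription of the published formula
it checks, deliberately written without reference to the package
implementation.
"""

from fractions import Fraction
from math import comb


def wc_components_oracle(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham (1984) variance components for one biallelic locus
    and two populations, transcribed literally from the published formulas.

    n_i: sample sizes (individuals), p_i: sample alt-allele frequencies,
    h_i: observed heterozygote fractions.
    """
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def hypergeom_upper_tail_exact(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact enumeration."""
    total = comb(N, n)
    s = Fraction(0)
    for i in range(k, min(K, n) + 1):
        s += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(s)


def pairwise_ehh_oracle(haps):
    """EHH by direct pair counting: fraction of haplotype pairs identical
    over the full extent of *haps* (list of tuples)."""
    n = len(haps)
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            if haps[i] == haps[j]:
                pairs += 1
    return pairs / (n * (n - 1) / 2)
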