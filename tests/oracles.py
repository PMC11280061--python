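"""Independent oracles: exact rational Fisher tail and naive step-up BH.

Deliberately simple and self-contained — these never share code with the
implementation they check.
"""

from fractions import Fraction
from math import comb


def exact_fisher_greater(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided (greater) Fisher p as an exact rational tail sum.

    P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+c, n=a+b), summed term by
    term with integer binomials.
    """
    n_total = a + b + c + d
    k_bound = a + c
    n_deg = a + b
    numer = sum(
        comb(k_bound, k) * comb(n_total - k_bound, n_deg - k)
        for k in range(a, min(k_bound, n_deg) + 1)
    )
    return min(Fraction(numer, comb(n_total, n_deg)), Fraction(1))


def naive_bh(pvalues):
    """Textbook step-up Benjamini-Hochberg, returned in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvalues[idx] * m / rank)
        q[idx] = val
        prev = val
    return q
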