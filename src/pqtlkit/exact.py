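"""Exact small-sample tests computed in rational arithmetic.

Floating-point enumeration can mis-rank outcomes whose probabilities are
equal up to rounding; for the table sizes this pipeline tests (HWE per
variant, Fisher on 2x2 counts), full enumeration with ``fractions`` is
cheap and removes the tie-handling ambiguity entirely.  Larger Fisher
tables fall back to scipy.
"""
from __future__ import annotations

from fractions import Fraction
from math import comb

from scipy import stats

from .errors import DomainError

#: Largest 2x2 table total for which the rational enumeration is used.
FISHER_EXACT_LIMIT = 500


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Enumerates every heterozygote count compatible with the observed
    allele totals (same parity) and sums the probabilities of outcomes no
    more likely than the observed one.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise DomainError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise DomainError("HWE test requires >= 1 sample")
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)

    weights: dict[int, Fraction] = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        # multinomial weight x 2^het; the shared constant cancels in the ratio
        weights[het] = Fraction(
            2 ** het * comb(n, het) * comb(n - het, hom_rare), 1)
    total = sum(weights.values())
    observed = weights[n_ab]
    p = sum(w for w in weights.values() if w <= observed) / total
    return float(min(p, Fraction(1)))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.  Returns
    (odds ratio, p); the odds ratio is inf when b*c == 0 and a*d > 0.
    """
    if min(a, b, c, d) < 0:
        raise DomainError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise DomainError("empty table")
    if n > FISHER_EXACT_LIMIT:
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float(odds), float(p)

    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    weights = {k: Fraction(comb(col1, k) * comb(n - col1, row1 - k), 1)
               for k in range(lo, hi + 1)}
    total = sum(weights.values())
    observed = weights[a]
    p = sum(w for w in weights.values() if w <= observed) / total
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(min(p, Fraction(1)))
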