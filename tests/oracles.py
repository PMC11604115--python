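"""Brute-force rarefaction oracles: exhaustive enumeration of all g-subsets
of the observed gene copies, exact rational arithmetic.

Used by the unit tests and the acceptance suite to pin the hypergeometric
rarefaction formulas against an implementation-independent ground truth.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from itertools import combinations


@lru_cache(maxsize=None)
def enum_present_prob(N: int, c: int, g: int) -> Fraction:
    """P(an allele with c of N copies appears in a uniform g-copy subset),
    by enumerating all C(N, g) subsets of labelled copies."""
    if not (0 <= c <= N and 2 <= g <= N):
        raise ValueError("bad enumeration configuration")
    pool = [1] * c + [0] * (N - c)
    hits = total = 0
    for combo in combinations(range(N), g):
        total += 1
        if any(pool[k] for k in combo):
            hits += 1
    return Fraction(hits, total)


def oracle_allele_count(copies, g: int) -> Fraction:
    """Expected distinct alleles in a g-copy subset (sum of presence probs)."""
    N = sum(copies)
    return sum((enum_present_prob(N, c, g) for c in copies), Fraction(0))


def oracle_absent_count(copies_i, N_i, copies_j, N_j, g: int) -> Fraction:
    """Expected alleles present in an independent g-subset of i's copies and
    absent from a g-subset of j's copies."""
    out = Fraction(0)
    for ci, cj in zip(copies_i, copies_j):
        out += enum_present_prob(N_i, ci, g) * (1 - enum_present_prob(N_j, cj, g))
    return out


def oracle_private(copies_by_pop, totals, g: int):
    """Per-subpopulation expected count of alleles present in its g-subset and
    absent from every other subpopulation's independent g-subset."""
    n = len(copies_by_pop)
    n_alleles = len(copies_by_pop[0])
    pres = [
        [enum_present_prob(totals[i], copies_by_pop[i][a], g) for a in range(n_alleles)]
        for i in range(n)
    ]
    out = []
    for i in range(n):
        acc = Fraction(0)
        for a in range(n_alleles):
            term = pres[i][a]
            for j in range(n):
                if j != i:
                    term *= 1 - pres[j][a]
            acc += term
        out.append(acc)
    return out
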