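"""Independent brute-force oracles used to cross-check the fast implementations.

The kinship oracle is Wright's path-counting method: enumerate every simple
ancestor path from each animal to each common ancestor A and sum
(1/2)^(n1 + n2 + 1) (1 + F_A) over pairs of paths that share no animal except
A.  It is deliberately independent of the tabular recursion it checks.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache

from pedvar.pedigree import Pedigree


class PathKinshipOracle:
    """Exact coancestry by ancestor-path enumeration (dyadic rationals)."""

    def __init__(self, ped: Pedigree):
        self.ped = ped
        n = len(ped)
        # all simple ancestor paths per animal: (ancestor, node-bitmask, length)
        self.paths: list[list[tuple[int, int, int]]] = [None] * n
        for i in ped.topo:
            out = [(i, 1 << i, 0)]
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    out.extend((anc, mask | (1 << i), ln + 1)
                               for anc, mask, ln in self.paths[p])
            self.paths[i] = out

    @lru_cache(maxsize=None)
    def inbreeding(self, i: int) -> Fraction:
        s, d = self.ped.sire[i], self.ped.dam[i]
        if s < 0 or d < 0:
            return Fraction(0)
        return self.kinship(int(s), int(d))

    @lru_cache(maxsize=None)
    def kinship(self, i: int, j: int) -> Fraction:
        if i == j:
            return Fraction(1, 2) * (1 + self.inbreeding(i))
        total = Fraction(0)
        by_anc_j: dict[int, list[tuple[int, int]]] = {}
        for anc, mask, ln in self.paths[j]:
            by_anc_j.setdefault(anc, []).append((mask, ln))
        for anc, mask_i, len_i in self.paths[i]:
            for mask_j, len_j in by_anc_j.get(anc, ()):
                if mask_i & mask_j == (1 << anc):      # disjoint except at A
                    total += (Fraction(1, 2) ** (len_i + len_j + 1)
                              * (1 + self.inbreeding(anc)))
        return total


def levene_two_allele_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-allele HWE p-value from the closed-form conditional
    distribution of the heterozygote count given allele counts."""
    from math import comb

    n = n_aa + n_ab + n_bb
    m_a = 2 * n_aa + n_ab
    m_b = 2 * n_bb + n_ab

    def prob(h: int) -> float:
        # h must match the parity of m_a and leave integer homozygote counts
        if (m_a - h) % 2 or h > min(m_a, m_b) or (m_a - h) < 0 or (m_b - h) < 0:
            return 0.0
        aa = (m_a - h) // 2
        bb = (m_b - h) // 2
        # n! 2^h / (aa! h! bb!) * m_a! m_b! / (2n)!  via exact integers
        from math import factorial
        num = factorial(n) * 2 ** h * factorial(m_a) * factorial(m_b)
        den = factorial(aa) * factorial(h) * factorial(bb) * factorial(2 * n)
        return num / den

    p_obs = prob(n_ab)
    return sum(prob(h) for h in range(0, min(m_a, m_b) + 1)
               if prob(h) <= p_obs + 1e-12)
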