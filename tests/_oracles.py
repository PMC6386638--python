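"""Independent brute-force oracles used to validate the implementations.

Each oracle recomputes a quantity from first principles by a different
route than the library code: transmission enumeration for inheritance
calls, full hypergeometric enumeration for Fisher's exact test, binomial
tail root-finding for Clopper-Pearson bounds, and pair-count permutation
for the Mann-Whitney statistic.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

# genotype -> multiset of alleles (0 = ref, 1 = alt)
ALLELES = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}


def transmission_oracle(gf: str, gm: str, gp: str) -> str:
    """Expected trio inheritance call by enumerating allele transmissions.

    Each parent transmits one of their two alleles.  A fetal genotype is
    Mendelian-consistent if some transmission pair reproduces it; a de
    novo heterozygote additionally requires both parents to possess a
    reference allele (one transmitted allele mutated).  Inheritance is
    called by parsimony: an available transmission explanation beats a de
    novo one.
    """
    fetus = tuple(sorted(ALLELES[gf]))
    gm_a, gp_a = ALLELES[gm], ALLELES[gp]
    if fetus == (0, 0):
        return "uninformative"
    origins = set()
    for tm in set(gm_a):
        for tp in set(gp_a):
            if tuple(sorted((tm, tp))) == fetus:
                if fetus == (1, 1):
                    origins.add("both")
                elif tm == 1:
                    origins.add("M")
                else:
                    origins.add("F")
    if fetus == (1, 1):
        return "biallelic_homozygous" if origins else "mendelian_inconsistent"
    # fetus het
    if origins == {"M"}:
        return "inherited_maternal"
    if origins == {"F"}:
        return "inherited_paternal"
    if origins == {"M", "F"}:
        return "uninformative"
    # no transmission explains the het: de novo iff both parents can
    # transmit a ref allele that mutated
    if 0 in gm_a and 0 in gp_a:
        return "de_novo"
    return "mendelian_inconsistent"


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of same-margin tables."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def clopper_pearson_oracle(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """CP bounds by direct root-finding on the binomial tail probabilities."""
    alpha = 1.0 - level
    if k == 0:
        lo = 0.0
    else:
        lo = brentq(lambda p: binom.sf(k - 1, n, p) - alpha / 2, 1e-15, 1 - 1e-15,
                    xtol=1e-13)
    if k == n:
        hi = 1.0
    else:
        hi = brentq(lambda p: binom.cdf(k, n, p) - alpha / 2, 1e-15, 1 - 1e-15,
                    xtol=1e-13)
    return float(lo), float(hi)


def mann_whitney_permutation_oracle(a, b) -> float:
    """Two-sided exact p via the pair-count definition of U.

    U counts pairs (x in A, y in B) with x > y, plus half the ties; the
    permutation distribution enumerates every split of the pooled sample.
    """
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n1 = len(a)
    n = len(pooled)

    def u_stat(idx_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx_a)] = True
        xs, ys = pooled[mask], pooled[~mask]
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    mu = n1 * (n - n1) / 2.0
    u_obs = u_stat(range(n1))
    dev = abs(u_obs - mu) - 1e-12
    hits = total = 0
    for idx in combinations(range(n), n1):
        if abs(u_stat(idx) - mu) >= dev:
            hits += 1
        total += 1
    return hits / total
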