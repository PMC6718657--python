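"""Independent oracle implementations used only by the tests.

Each oracle takes a deliberately different computational route from the
package code it checks: exact rational enumeration for the HWE test, direct
simulation of random allele pairings, an explicit step-by-step running sum
for enrichment scores, textbook Cox-de Boor recursion for the B-spline basis,
and a declarative fixed-point rule for LD pruning.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by full enumeration with rational arithmetic.

    P(h het | allele counts) = n! / (nAA! h! naa!) * 2^h * nA! na! / (2n)!
    computed as exact Fractions; the p-value sums configurations whose
    probability is <= the observed one.
    """
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    nA = 2 * n - na
    if min(na, nA) == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        rest = min(na, nA) - h
        if rest < 0 or rest % 2:
            return Fraction(0)
        n_minor_hom = rest // 2
        n_major_hom = n - h - n_minor_hom
        if n_major_hom < 0:
            return Fraction(0)
        num = (
            math.factorial(n)
            * 2**h
            * math.factorial(nA)
            * math.factorial(na)
        )
        den = (
            math.factorial(n_major_hom)
            * math.factorial(h)
            * math.factorial(n_minor_hom)
            * math.factorial(2 * n)
        )
        return Fraction(num, den)

    lo = min(na, nA)
    hets = [h for h in range(lo % 2, lo + 1, 2)]
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def hwe_mc_p(
    n_AA: int, n_Aa: int, n_aa: int, n_draws: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo HWE p-value by random pairings of the observed alleles.

    A uniformly random perfect matching of the 2n alleles into n genotypes is
    sampled via two nested hypergeometric draws: U = number of pairs whose
    first slot carries the minor allele, then V = overlap between the
    first-slot and second-slot minor-allele pair sets; the heterozygote count
    is na - 2V.  Equivalence with direct allele shuffling is asserted by a
    unit test.  Returns (p_estimate, MC standard error).
    """
    n = n_AA + n_Aa + n_aa
    na = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if na == 0:
        return 1.0, 0.0
    U = rng.hypergeometric(na, 2 * n - na, n, size=n_draws)
    V = rng.hypergeometric(U, n - U, np.maximum(na - U, 0))
    hets = na - 2 * V
    # a draw counts when its configuration is no more probable than the
    # observed one; the ordering statistic is the closed-form conditional
    # probability (the standard Monte-Carlo exact-test construction)
    logT = {h: _log_conditional_prob(n, na, h) for h in range(na % 2, na + 1, 2)}
    t_obs = logT[n_Aa]
    extreme = np.array(
        [h for h, t in logT.items() if t <= t_obs + 1e-9], dtype=np.int64
    )
    counts = np.bincount(hets, minlength=na + 1)
    p_hat = counts[extreme].sum() / n_draws
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_draws)
    return float(p_hat), se


def _log_conditional_prob(n: int, na: int, h: int) -> float:
    """log P(h heterozygotes | allele counts), via binomial coefficients."""
    rest = na - h
    if rest < 0 or rest % 2:
        return math.inf
    n_min_hom = rest // 2
    n_maj_hom = n - h - n_min_hom
    if n_maj_hom < 0:
        return math.inf
    num = math.comb(n, h) * math.comb(n - h, n_min_hom) * 2**h
    den = math.comb(2 * n, na)
    return math.log(num) - math.log(den)


def pairing_het_counts_direct(
    n_minor: int, n_major: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Reference sampler: shuffle the allele multiset, pair adjacent slots."""
    n = (n_minor + n_major) // 2
    alleles = np.r_[np.ones(n_minor, np.int8), np.zeros(n_major, np.int8)]
    out = np.empty(n_draws, np.int64)
    for b in range(n_draws):
        out[b] = (rng.permutation(alleles).reshape(n, 2).sum(1) == 1).sum()
    return out


def pairing_het_counts_fast(
    n_minor: int, n_major: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """The nested-hypergeometric sampler used by hwe_mc_p."""
    n = (n_minor + n_major) // 2
    U = rng.hypergeometric(n_minor, n_major, n, size=n_draws)
    V = rng.hypergeometric(U, n - U, np.maximum(n_minor - U, 0))
    return n_minor - 2 * V


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def running_sum_es(ranked: list[tuple[str, float]], members: set[str]) -> float:
    """Step-by-step weighted KS walk, scalar arithmetic only."""
    hit_total = sum(s for g, s in ranked if g in members)
    n_hit = sum(1 for g, _ in ranked if g in members)
    n_miss = len(ranked) - n_hit
    running, best = 0.0, 0.0
    for g, s in ranked:
        if g in members:
            running += (s / hit_total) if hit_total > 0 else (1.0 / n_hit)
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


# ---------------------------------------------------------------------------
# B-spline basis (Cox-de Boor recursion)
# ---------------------------------------------------------------------------

def deboor_basis(x: float, knots: np.ndarray, degree: int) -> np.ndarray:
    """Evaluate all B-spline basis functions at x by the textbook recursion."""
    n_basis = len(knots) - degree - 1
    # degree 0
    b = np.zeros((len(knots) - 1,))
    for i in range(len(knots) - 1):
        if knots[i] <= x < knots[i + 1]:
            b[i] = 1.0
    if x == knots[-1]:  # closed right edge
        for i in range(len(knots) - 2, -1, -1):
            if knots[i] < knots[i + 1]:
                b[i] = 1.0
                break
    for d in range(1, degree + 1):
        nb = np.zeros(len(knots) - d - 1)
        for i in range(len(nb)):
            left = 0.0
            if knots[i + d] != knots[i]:
                left = (x - knots[i]) / (knots[i + d] - knots[i]) * b[i]
            right = 0.0
            if knots[i + d + 1] != knots[i + 1]:
                right = (
                    (knots[i + d + 1] - x)
                    / (knots[i + d + 1] - knots[i + 1])
                    * b[i + 1]
                )
            nb[i] = left + right
        b = nb
    return b[:n_basis]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def brute_force_prune(
    dosage: np.ndarray,
    pos: np.ndarray,
    window_bp: float,
    r2_max: float,
) -> list[int]:
    """Fixed point of the declarative removal rule, all pairs considered.

    While any kept pair within window_bp has r2 > r2_max, remove from the
    variants involved in violations the one with the lowest MAF (ties broken
    by later position).  Single chromosome assumed.
    """
    m = dosage.shape[1]
    freq = np.nanmean(dosage, axis=0) / 2
    maf = np.minimum(freq, 1 - freq)

    def r2(i, j):
        a, b = dosage[:, i], dosage[:, j]
        ok = ~np.isnan(a) & ~np.isnan(b)
        if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
            return 0.0
        return float(np.corrcoef(a[ok], b[ok])[0, 1] ** 2)

    kept = set(range(m))
    while True:
        violating = set()
        ks = sorted(kept)
        for ai in range(len(ks)):
            for bi in range(ai + 1, len(ks)):
                i, j = ks[ai], ks[bi]
                if abs(pos[j] - pos[i]) <= window_bp and r2(i, j) > r2_max:
                    violating |= {i, j}
        if not violating:
            return sorted(kept)
        drop = min(violating, key=lambda k: (maf[k], -pos[k]))
        kept.discard(drop)
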