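"""Independent reference implementations used only to check the package.

Each oracle is written directly from the defining formula, scalar-wise and
with exact arithmetic where feasible, deliberately sharing no code with the
implementations it validates.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import stats as sstats


def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact-rational HWE p-value by full enumeration of heterozygote counts.

    P(n_ab | n_A, n) = n! / (n_AA! n_ab! n_bb!) * 2^n_ab / C(2n, n_A);
    the p-value sums every configuration whose probability does not exceed
    the observed one.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def prob(h: int) -> Fraction:
        aa = (n_a - h) // 2
        bb = n - aa - h
        num = Fraction(math.factorial(n), math.factorial(aa) * math.factorial(h) * math.factorial(bb))
        return num * Fraction(2**h) / Fraction(math.comb(2 * n, n_a))

    hs = [h for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
          if (n_a - h) // 2 >= 0 and n - (n_a - h) // 2 - h >= 0]
    probs = {h: prob(h) for h in hs}
    obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= obs)


def wc_abc_oracle(genotypes_by_pop: list[list[int]]):
    """Weir & Cockerham (1984) a/b/c for one biallelic locus, scalar-wise.

    ``genotypes_by_pop`` holds called 0/1/2 genotypes per population (missing
    already removed).  Populations without data are skipped.  Returns
    (a, b, c) or None when fewer than two populations carry data.
    """
    pops = [g for g in genotypes_by_pop if len(g) > 0]
    r = len(pops)
    if r < 2:
        return None
    n_i = [len(g) for g in pops]
    p_i = [sum(g) / (2 * len(g)) for g in pops]
    h_i = [sum(1 for x in g if x == 1) / len(g) for g in pops]
    nbar = sum(n_i) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - sum(n**2 for n in n_i) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def bh_stepup_oracle(pvals) -> np.ndarray:
    """Brute-force BH q-values: q_i = min over thresholds t >= p_i of
    m * t / #{p <= t}, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        candidates = [
            m * t / np.sum(p <= t) for t in p if t >= p[i] - 1e-15
        ]
        q[i] = min(1.0, min(candidates))
    return q


def gaussian_aic_oracle(y: np.ndarray, X: np.ndarray) -> float:
    """AIC via an explicit normal log-likelihood at the OLS MLE.

    Fits OLS, sets sigma^2 to RSS/n, sums norm.logpdf over residuals, and
    returns 2k - 2 lnL with k = #coefficients + 1 for sigma.
    """
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n = len(y)
    sigma2 = float((resid**2).sum() / n)
    loglik = float(sstats.norm.logpdf(resid, loc=0, scale=math.sqrt(sigma2)).sum())
    k = X.shape[1] + 1
    return 2 * k - 2 * loglik


def paralog_het_oracle(p1: float, p2: float) -> float:
    """Apparent heterozygote proportion of a merged duplicate locus.

    Enumerates the 9 two-locus genotype pairs; the merged call is
    heterozygous unless all four allele copies agree.
    """
    total = 0.0
    for g1, pr1 in _binom2(p1):
        for g2, pr2 in _binom2(p2):
            copies = g1 + g2
            if 0 < copies < 4:
                total += pr1 * pr2
    return total


def _binom2(p: float):
    return [(0, (1 - p) ** 2), (1, 2 * p * (1 - p)), (2, p**2)]
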