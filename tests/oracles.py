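"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package: exact-fraction
enumeration for the Hardy-Weinberg test, a dense Bayes-rule posterior
computation, and a plain sort-and-pick panel selector.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def hwe_enumeration_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-fraction enumeration over all heterozygote configurations.

    Conditional on n diploids and the allele counts, the probability of
    h heterozygotes is  C-multinomial(n; hom_r, h, hom_c) * 2^h divided
    by C(2n, rare).  The two-sided p-value sums configurations no more
    probable than the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa
    rare = min(n_a, 2 * n - n_a)
    common = 2 * n - rare
    if rare == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        hom_r = (rare - h) // 2
        hom_c = (common - h) // 2
        multi = (
            comb(n, h) * comb(n - h, hom_r)
        )  # n! / (h! hom_r! hom_c!)
        return Fraction(multi * 2**h, comb(2 * n, rare))

    hs = list(range(rare % 2, rare + 1, 2))
    probs = {h: prob(h) for h in hs}
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


def bayes_posteriors(
    x: np.ndarray,
    means: np.ndarray,
    cov: np.ndarray,
    priors: np.ndarray,
) -> np.ndarray:
    """Dense shared-covariance Gaussian posteriors via explicit inverse.

    Computes the full (unnormalized, un-logged) Gaussian density per
    class and normalizes row-wise — numerically naive on purpose.
    """
    inv = np.linalg.inv(cov)
    n, c = x.shape[0], means.shape[0]
    unnorm = np.empty((n, c))
    for k in range(c):
        d = x - means[k]
        maha = np.sum(d @ inv * d, axis=1)
        unnorm[:, k] = priors[k] * np.exp(-0.5 * maha)
    return unnorm / unnorm.sum(axis=1, keepdims=True)


def sort_and_pick_panel(
    freq: dict[str, dict[str, float]],
    scheme: list[tuple[tuple[str, str], int]],
    exclude: set[str] | None = None,
) -> list[tuple[str, tuple[str, str], float]]:
    """Exhaustive selection oracle: for each (pair, count) slot in
    order, compute every SNP's |p_i - p_j|, sort (delta desc, snp_id
    asc), and pick the top `count` SNPs not yet taken."""
    taken = set(exclude or ())
    picked: list[tuple[str, tuple[str, str], float]] = []
    for (pi, pj), count in scheme:
        deltas = []
        for snp in freq[pi]:
            a, b = freq[pi][snp], freq[pj][snp]
            if a != a or b != b:  # NaN
                continue
            deltas.append((snp, abs(a - b)))
        deltas.sort(key=lambda t: (-t[1], t[0]))
        filled = 0
        for snp, d in deltas:
            if filled == count:
                break
            if snp in taken:
                continue
            picked.append((snp, (pi, pj), d))
            taken.add(snp)
            filled += 1
        assert filled == count, f"oracle could not fill pair {(pi, pj)}"
    return picked
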