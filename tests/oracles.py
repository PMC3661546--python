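"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the
library: exact rational enumeration for the Hardy-Weinberg test, a
scalar transcription of the Weir-Cockerham variance components,
exhaustive simplex-grid search for EM likelihoods, and a windowed
brute-force four-gamete partitioner.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by rational enumeration over heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0
    weights: dict[int, Fraction] = {}
    for h in range(nA % 2, min(nA, na) + 1, 2):
        a = (nA - h) // 2
        w = Fraction(comb(n, a) * comb(n - a, h) * 2**h)
        weights[h] = w
    total = sum(weights.values())
    p_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


def wc_theta_oracle(
    counts_i: tuple[int, int, int], counts_j: tuple[int, int, int]
) -> float:
    """Plain-scalar transcription of the 1984 two-population theta."""
    n1, n2 = sum(counts_i), sum(counts_j)
    p1 = (2 * counts_i[2] + counts_i[1]) / (2 * n1)
    p2 = (2 * counts_j[2] + counts_j[1]) / (2 * n2)
    h1, h2 = counts_i[1] / n1, counts_j[1] / n2
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
    return a / (a + b + c)


# ---------------------------------------------------------------------------
# Simplex-grid likelihood oracle
# ---------------------------------------------------------------------------


def _simplex_grid(k: int, m: int) -> np.ndarray:
    """All compositions of m into k nonnegative parts, as an (N, k) array."""
    out = []
    for cuts in itertools.combinations(range(m + k - 1), k - 1):
        prev = -1
        parts = []
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(m + k - 2 - prev)
        out.append(parts)
    return np.asarray(out, dtype=float)


def _grid_resolution(k: int) -> int:
    # keep grids under ~5e5 points while staying as fine as affordable
    return {1: 1, 2: 1000, 3: 1000, 4: 100, 5: 40, 6: 25, 7: 18, 8: 14}.get(k, 10)


def multilocus_loglik(
    genotypes: list[tuple[int, ...]],
    haplotypes: list[tuple[int, ...]],
    freqs: np.ndarray,
) -> np.ndarray:
    """Log-likelihood of unphased genotypes under haplotype frequencies.

    ``freqs`` is (N, len(haplotypes)); returns one log-likelihood per
    frequency vector.  Haplotype pairs not representable in
    ``haplotypes`` contribute zero probability.
    """
    hap_index = {h: i for i, h in enumerate(haplotypes)}
    ll = np.zeros(freqs.shape[0])
    for geno in genotypes:
        prob = np.zeros(freqs.shape[0])
        for h1, h2 in compatible_pairs_oracle(geno):
            if h1 in hap_index and h2 in hap_index:
                coef = 1.0 if h1 == h2 else 2.0
                prob = prob + coef * freqs[:, hap_index[h1]] * freqs[:, hap_index[h2]]
        with np.errstate(divide="ignore"):
            ll = ll + np.log(prob)
    return ll


def compatible_pairs_oracle(geno: tuple[int, ...]):
    """Unordered haplotype pairs consistent with a multilocus genotype."""
    hets = [i for i, g in enumerate(geno) if g == 1]
    if not hets:
        h = tuple(g // 2 for g in geno)
        return [(h, h)]
    pairs = set()
    for bits in itertools.product((0, 1), repeat=len(hets)):
        h1 = list(g // 2 if g != 1 else 0 for g in geno)
        h2 = list(h1)
        for site, bit in zip(hets, bits):
            h1[site], h2[site] = bit, 1 - bit
        pairs.add(tuple(sorted((tuple(h1), tuple(h2)))))
    return sorted(pairs)


def grid_max_loglik(
    genotypes: list[tuple[int, ...]], haplotypes: list[tuple[int, ...]]
) -> float:
    """Best log-likelihood over an exhaustive simplex grid of frequencies."""
    k = len(haplotypes)
    m = _grid_resolution(k)
    grid = _simplex_grid(k, m) / m
    ll = multilocus_loglik(genotypes, haplotypes, grid)
    return float(np.max(ll))


def spectrum_loglik(
    genotypes: list[tuple[int, ...]], spectrum: dict[tuple[int, ...], float]
) -> float:
    """Log-likelihood of a haplotype spectrum for the same genotypes."""
    haps = sorted(spectrum)
    f = np.asarray([[spectrum[h] for h in haps]])
    return float(multilocus_loglik(genotypes, haps, f)[0])


def support_haplotypes(genotypes: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    """Haplotypes compatible with at least one individual.

    Haplotypes outside this set receive zero mass at any likelihood
    maximum, so restricting the grid to it loses nothing.
    """
    support = set()
    for g in genotypes:
        for h1, h2 in compatible_pairs_oracle(g):
            support.add(h1)
            support.add(h2)
    return sorted(support)


# ---------------------------------------------------------------------------
# Brute-force four-gamete partitioner
# ---------------------------------------------------------------------------


def brute_force_partition(pair_passes, n: int) -> list[list[int]]:
    """Greedy maximal contiguous runs, re-checking every pair per window."""
    blocks: list[list[int]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and all(
            pair_passes(a, b)
            for a in range(i, j + 2)
            for b in range(a + 1, j + 2)
        ):
            j += 1
        if j > i:
            blocks.append(list(range(i, j + 1)))
        i = j + 1 if j > i else i + 1
    return blocks
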