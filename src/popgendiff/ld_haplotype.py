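"""Linkage-disequilibrium features of a gene region in one population.

Haplotype frequencies are estimated from unphased genotypes by
expectation-maximization: a two-locus EM for pairwise r-squared and
D-prime, and a multi-locus EM (direct enumeration up to a size limit,
partition-ligation beyond it) for block haplotype spectra.  Haplotype
blocks are maximal contiguous SNP runs in which every pair shows fewer
than four gametes above a frequency threshold (the four-gamete test);
block-level summaries (count, mean span, SNP density, haplotype
diversity) complete the LD feature set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GeneRegion, VariantTable

EM_TOL = 1e-8
EM_MAX_ITER = 1000

#: A fourth gamete "exists" if its EM frequency reaches this value.
DEFAULT_FOURTH_GAMETE_THRESHOLD = 0.01

#: Blocks longer than this use partition-ligation EM.
DEFAULT_PL_THRESHOLD = 8


@dataclass
class PairwiseLD:
    snp_a: int
    snp_b: int
    hap_freqs: np.ndarray  # shape (2,2); [a,b] = freq of haplotype with alleles a,b
    r2: float
    d_prime: float


@dataclass
class HaplotypeBlock:
    snp_indices: np.ndarray  # contiguous VariantTable column indices
    start_bp: int
    end_bp: int
    hap_spectrum: dict[tuple[int, ...], float]
    n_chromosomes: int

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class GeneLDFeatures:
    gene_id: str
    population: str
    block_number: float
    mean_block_size: float
    snp_density: float
    haplotype_diversity: float
    pair_r2: dict[tuple[int, int], float] = field(default_factory=dict)
    pair_dprime: dict[tuple[int, int], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Two-locus EM and LD coefficients
# ---------------------------------------------------------------------------


def em_two_locus(dos_a: np.ndarray, dos_b: np.ndarray) -> np.ndarray:
    """ML four-haplotype frequencies from unphased two-locus genotypes.

    Returns a (2,2) array ``f`` with ``f[x, y]`` the frequency of the
    haplotype carrying allele ``x`` at the first locus and ``y`` at the
    second (0 = ref, 1 = alt).  Samples missing at either locus are
    dropped.  Initialization is the linkage-equilibrium product of the
    observed allele frequencies; iteration stops when the largest
    frequency change falls below 1e-8.
    """
    dos_a = np.asarray(dos_a)
    dos_b = np.asarray(dos_b)
    ok = (dos_a != MISSING) & (dos_b != MISSING)
    a, b = dos_a[ok], dos_b[ok]
    if len(a) < 2:
        raise ValueError("need >=2 samples non-missing at both SNPs")
    # 3x3 genotype cross-tabulation
    n = np.zeros((3, 3), dtype=float)
    np.add.at(n, (a.astype(int), b.astype(int)), 1.0)
    total_hap = 2.0 * len(a)

    pA = (2 * n[2, :].sum() + n[1, :].sum()) / total_hap  # alt freq, locus a
    pB = (2 * n[:, 2].sum() + n[:, 1].sum()) / total_hap
    f = np.array(
        [
            [(1 - pA) * (1 - pB), (1 - pA) * pB],
            [pA * (1 - pB), pA * pB],
        ]
    )
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return f  # degenerate: one locus monomorphic

    # Unambiguous haplotype counts from all cells except the double het.
    base = np.zeros((2, 2))
    for ga in range(3):
        for gb in range(3):
            if (ga, gb) == (1, 1) or n[ga, gb] == 0:
                continue
            ha = [0, 1] if ga == 1 else [ga // 2, ga // 2]
            hb = [0, 1] if gb == 1 else [gb // 2, gb // 2]
            for x, y in zip(ha, hb):
                base[x, y] += n[ga, gb]
    n_dh = n[1, 1]
    for _ in range(EM_MAX_ITER):
        cis = f[0, 0] * f[1, 1]
        trans = f[0, 1] * f[1, 0]
        denom = cis + trans
        w = 0.5 if denom == 0 else cis / denom
        new = base.copy()
        new[0, 0] += n_dh * w
        new[1, 1] += n_dh * w
        new[0, 1] += n_dh * (1 - w)
        new[1, 0] += n_dh * (1 - w)
        new /= total_hap
        if np.max(np.abs(new - f)) < EM_TOL:
            f = new
            break
        f = new
    return f


def ld_stats(hap_freqs: np.ndarray) -> tuple[float, float]:
    """(r-squared, D-prime) from four haplotype frequencies.

    D = f_AB - p_A p_B; r2 = D^2 / (p_A(1-p_A) p_B(1-p_B)); D' = |D| /
    D_max.  A monomorphic marginal makes both undefined (NaN, NaN).
    """
    f = np.asarray(hap_freqs, dtype=float)
    pA = f[1, :].sum()
    pB = f[:, 1].sum()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return float("nan"), float("nan")
    d = f[1, 1] - pA * pB
    r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
    if d > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    elif d < 0:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return 0.0, 0.0
    return float(r2), float(abs(d) / d_max)


def pairwise_ld(
    vt: VariantTable,
    sample_rows: np.ndarray,
    snp_indices: np.ndarray,
    max_pair_distance: int | None = None,
) -> dict[tuple[int, int], PairwiseLD]:
    """All-pairs EM haplotype frequencies and LD coefficients.

    Keys are (snp_a, snp_b) with snp_a < snp_b (VariantTable column
    indices).  ``max_pair_distance`` (bp) optionally skips distant
    pairs on large regions.
    """
    out: dict[tuple[int, int], PairwiseLD] = {}
    g = vt.genotypes[sample_rows, :]
    for ia, ib in itertools.combinations(range(len(snp_indices)), 2):
        sa, sb = int(snp_indices[ia]), int(snp_indices[ib])
        if max_pair_distance is not None and abs(int(vt.pos[sb] - vt.pos[sa])) > max_pair_distance:
            continue
        f = em_two_locus(g[:, sa], g[:, sb])
        r2, dp = ld_stats(f)
        out[(sa, sb)] = PairwiseLD(snp_a=sa, snp_b=sb, hap_freqs=f, r2=r2, d_prime=dp)
    return out


# ---------------------------------------------------------------------------
# Four-gamete blocks
# ---------------------------------------------------------------------------


def _pair_passes(
    ld: dict[tuple[int, int], PairwiseLD], sa: int, sb: int, threshold: float
) -> bool:
    key = (sa, sb) if sa < sb else (sb, sa)
    pair = ld.get(key)
    if pair is None:
        return True  # out-of-range pairs never break a block
    return int(np.sum(pair.hap_freqs >= threshold)) < 4


def four_gamete_blocks(
    vt: VariantTable,
    sample_rows: np.ndarray,
    gene: GeneRegion,
    fourth_gamete_threshold: float = DEFAULT_FOURTH_GAMETE_THRESHOLD,
    pl_threshold: int = DEFAULT_PL_THRESHOLD,
    ld: dict[tuple[int, int], PairwiseLD] | None = None,
) -> list[HaplotypeBlock]:
    """Greedy left-to-right four-gamete-test block partition.

    Blocks are maximal contiguous runs in which every SNP pair shows
    fewer than four gametes with EM frequency >=
    ``fourth_gamete_threshold``.  Singleton SNPs that extend no block
    are not reported.  Each block carries its EM haplotype spectrum.
    """
    snps = gene.snp_indices
    if len(snps) < 2:
        raise ValueError("gene slice needs >=2 SNPs")
    if ld is None:
        ld = pairwise_ld(vt, sample_rows, snps)
    blocks: list[list[int]] = []
    current = [int(snps[0])]
    for s in snps[1:]:
        s = int(s)
        if all(_pair_passes(ld, prev, s, fourth_gamete_threshold) for prev in current):
            current.append(s)
        else:
            if len(current) >= 2:
                blocks.append(current)
            current = [s]
    if len(current) >= 2:
        blocks.append(current)

    out: list[HaplotypeBlock] = []
    for members in blocks:
        cols = np.asarray(members, dtype=np.int64)
        spectrum, n_chrom = em_block_haplotypes(
            vt.genotypes[np.ix_(sample_rows, cols)], pl_threshold=pl_threshold
        )
        out.append(
            HaplotypeBlock(
                snp_indices=cols,
                start_bp=int(vt.pos[cols[0]]),
                end_bp=int(vt.pos[cols[-1]]),
                hap_spectrum=spectrum,
                n_chromosomes=n_chrom,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Multi-locus EM
# ---------------------------------------------------------------------------


def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All (h1, h2) haplotype pairs consistent with a multilocus genotype."""
    het_sites = [i for i, g in enumerate(geno) if g == 1]
    fixed = {i: g // 2 for i, g in enumerate(geno) if g != 1}
    pairs = []
    if not het_sites:
        h = tuple(fixed[i] for i in range(len(geno)))
        return [(h, h)]
    # fix the first het site to 0 on h1 to avoid double-counting orderings
    first, rest = het_sites[0], het_sites[1:]
    for bits in itertools.product((0, 1), repeat=len(rest)):
        h1 = list(geno)
        h2 = list(geno)
        h1[first], h2[first] = 0, 1
        for site, bit in zip(rest, bits):
            h1[site], h2[site] = bit, 1 - bit
        for i, v in fixed.items():
            h1[i] = h2[i] = v
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def _em_over_pairs(
    pair_lists: list[list[tuple[tuple[int, ...], tuple[int, ...]]]],
    init: dict[tuple[int, ...], float],
) -> dict[tuple[int, ...], float]:
    """EM over per-individual compatible haplotype-pair lists."""
    haps = sorted(init)
    index = {h: i for i, h in enumerate(haps)}
    f = np.array([init[h] for h in haps], dtype=float)
    f /= f.sum()
    n_ind = len(pair_lists)
    pair_idx = [
        np.array([[index[h1], index[h2]] for h1, h2 in pl], dtype=np.int64)
        for pl in pair_lists
    ]
    for _ in range(EM_MAX_ITER):
        new = np.zeros_like(f)
        for pidx in pair_idx:
            w = f[pidx[:, 0]] * f[pidx[:, 1]]
            if pidx.shape[0] > 1:
                w = w * np.array([2.0 if i != j else 1.0 for i, j in pidx])
            tot = w.sum()
            w = np.full(len(w), 1.0 / len(w)) if tot == 0 else w / tot
            np.add.at(new, pidx[:, 0], w)
            np.add.at(new, pidx[:, 1], w)
        new /= 2.0 * n_ind
        if np.max(np.abs(new - f)) < EM_TOL:
            f = new
            break
        f = new
    return {h: float(f[i]) for h, i in index.items() if f[i] > 0}


def em_block_haplotypes(
    block_genotypes: np.ndarray,
    pl_threshold: int = DEFAULT_PL_THRESHOLD,
    pl_candidates: int = 64,
) -> tuple[dict[tuple[int, ...], float], int]:
    """ML haplotype spectrum of a block from unphased genotypes.

    ``block_genotypes`` is samples x SNPs dosages.  Individuals with any
    missing call in the block are excluded.  Blocks wider than
    ``pl_threshold`` SNPs are solved by partition-ligation: each half is
    solved recursively and the final EM runs over the ``pl_candidates``
    highest-product concatenated haplotypes (individuals incompatible
    with every candidate pair are dropped from the ligation step).

    Returns (spectrum, number of chromosomes used).
    """
    g = np.asarray(block_genotypes)
    complete = g[~np.any(g == MISSING, axis=1), :]
    if complete.shape[0] < 1:
        raise ValueError("no complete genotypes in block")
    genos = [tuple(int(x) for x in row) for row in complete]
    n_chrom = 2 * len(genos)
    n_snps = complete.shape[1]

    if n_snps <= pl_threshold:
        pair_lists = [_compatible_pairs(gn) for gn in genos]
        support = sorted({h for pl in pair_lists for p in pl for h in p})
        # linkage-equilibrium initialization from single-SNP frequencies
        p_alt = complete.mean(axis=0) / 2.0
        init = {
            h: float(np.prod([p_alt[i] if a else 1 - p_alt[i] for i, a in enumerate(h)]))
            for h in support
        }
        if all(v == 0 for v in init.values()):
            init = {h: 1.0 for h in support}
        return _em_over_pairs(pair_lists, init), n_chrom

    # partition-ligation
    mid = n_snps // 2
    left, _ = em_block_haplotypes(complete[:, :mid], pl_threshold, pl_candidates)
    right, _ = em_block_haplotypes(complete[:, mid:], pl_threshold, pl_candidates)
    combos = sorted(
        ((lf * rf, lh + rh) for lh, lf in left.items() for rh, rf in right.items()),
        reverse=True,
    )[:pl_candidates]
    candidates = {h for _, h in combos}
    pair_lists = []
    init = {h: max(f, 1e-12) for f, h in combos}
    for gn in genos:
        pl = [
            (h1, h2)
            for h1, h2 in _compatible_pairs(gn)
            if h1 in candidates and h2 in candidates
        ]
        if pl:
            pair_lists.append(pl)
    if not pair_lists:
        raise ValueError("partition-ligation found no compatible individuals")
    return _em_over_pairs(pair_lists, init), n_chrom


# ---------------------------------------------------------------------------
# Block summaries
# ---------------------------------------------------------------------------


def haplotype_diversity(hap_spectrum: dict[tuple[int, ...], float], n_chromosomes: int) -> float:
    """Nei's unbiased haplotype diversity H = n/(n-1) (1 - sum p^2)."""
    if n_chromosomes < 2:
        return 0.0
    p = np.array(list(hap_spectrum.values()), dtype=float)
    return float(n_chromosomes / (n_chromosomes - 1) * (1.0 - np.sum(p**2)))


def block_features(
    blocks: list[HaplotypeBlock], region_span: int | None = None
) -> tuple[float, float, float]:
    """(block_number, mean block span in bp, mean SNPs-per-kb of blocks).

    With zero blocks all three are NaN (the gene/population has no
    resolved block structure to summarize).
    """
    if not blocks:
        return float("nan"), float("nan"), float("nan")
    sizes = np.array([b.span_bp for b in blocks], dtype=float)
    dens = np.array([b.n_snps / (b.span_bp / 1000.0) for b in blocks])
    return float(len(blocks)), float(sizes.mean()), float(dens.mean())


def gene_ld_features(
    vt: VariantTable,
    sample_rows: np.ndarray,
    gene: GeneRegion,
    population: str,
    fourth_gamete_threshold: float = DEFAULT_FOURTH_GAMETE_THRESHOLD,
    pl_threshold: int = DEFAULT_PL_THRESHOLD,
    max_pair_distance: int | None = None,
) -> GeneLDFeatures:
    """All six LD features of one gene region in one population."""
    ld = pairwise_ld(vt, sample_rows, gene.snp_indices, max_pair_distance)
    blocks = four_gamete_blocks(
        vt, sample_rows, gene, fourth_gamete_threshold, pl_threshold, ld=ld
    )
    n_blk, mean_size, density = block_features(blocks, gene.span_bp)
    if blocks:
        div = float(
            np.mean([haplotype_diversity(b.hap_spectrum, b.n_chromosomes) for b in blocks])
        )
    else:
        div = float("nan")
    return GeneLDFeatures(
        gene_id=gene.gene_id,
        population=population,
        block_number=n_blk,
        mean_block_size=mean_size,
        snp_density=density,
        haplotype_diversity=div,
        pair_r2={k: v.r2 for k, v in ld.items()},
        pair_dprime={k: v.d_prime for k, v in ld.items()},
    )
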