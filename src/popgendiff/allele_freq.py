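"""Allele-frequency features: reference-oriented frequencies, the
mean-absolute frequency difference d_AF, and Weir-Cockerham FST.

The tracked allele at each SNP is the minor allele in a designated
reference population (ties go to the VCF alt allele); its frequency is
then reported in every population so the same allele is compared
throughout.  FST uses the Weir & Cockerham (1984) theta estimator for
two populations, combined across the SNPs of a gene as a ratio of
summed variance components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import (
    MISSING,
    GeneRegion,
    PopulationPanel,
    VariantTable,
    genotype_counts,
)


@dataclass
class FrequencyVector:
    """Per-SNP frequencies of the reference-oriented allele in one population."""

    gene_id: str
    population: str
    freqs: np.ndarray  # in [0, 1], one entry per gene SNP
    allele_counts: np.ndarray  # non-missing chromosomes per SNP

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.allele_counts = np.asarray(self.allele_counts, dtype=np.int64)


@dataclass
class ReferenceOrientation:
    reference_population: str
    track_alt: np.ndarray  # per SNP: True if the tracked allele is the VCF alt


def orient_and_frequencies(
    vt: VariantTable,
    panel: PopulationPanel,
    gene: GeneRegion,
    reference_population: str,
) -> tuple[list[FrequencyVector], ReferenceOrientation]:
    """Reference-oriented allele frequencies for each population.

    The tracked allele at each SNP is the minor allele in
    ``reference_population`` (alt on a 0.5 tie).  Raises if any SNP has
    zero non-missing chromosomes in some population.
    """
    if reference_population not in panel.populations:
        raise ValueError(f"unknown reference population {reference_population!r}")
    if gene.n_snps < 2:
        raise ValueError(f"gene {gene.gene_id} has <2 SNPs")
    rows_by_pop = panel.sample_indices(vt)
    sub = vt.genotypes[:, gene.snp_indices]

    def _alt_freq(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = sub[rows, :]
        non_missing = (g != MISSING).sum(axis=0)
        alt = np.where(g == MISSING, 0, g).sum(axis=0)
        chroms = 2 * non_missing
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(chroms > 0, alt / np.maximum(chroms, 1), np.nan)
        return freq, chroms

    ref_freq, ref_chroms = _alt_freq(rows_by_pop[reference_population])
    _check_covered(ref_chroms, gene, reference_population)
    track_alt = ref_freq <= 0.5  # tie -> alt

    out: list[FrequencyVector] = []
    for pop in panel.populations:
        freq, chroms = _alt_freq(rows_by_pop[pop])
        _check_covered(chroms, gene, pop)
        oriented = np.where(track_alt, freq, 1.0 - freq)
        out.append(
            FrequencyVector(
                gene_id=gene.gene_id,
                population=pop,
                freqs=oriented,
                allele_counts=chroms,
            )
        )
    return out, ReferenceOrientation(reference_population, track_alt)


def _check_covered(chroms: np.ndarray, gene: GeneRegion, pop: str) -> None:
    bad = np.where(chroms == 0)[0]
    if len(bad):
        raise ValueError(
            f"gene {gene.gene_id}: SNP index {int(gene.snp_indices[bad[0]])} has no "
            f"non-missing genotypes in population {pop!r}"
        )


def maf_difference(fv_i: FrequencyVector, fv_j: FrequencyVector) -> float:
    """d_AF: mean absolute per-SNP difference of oriented frequencies."""
    if len(fv_i.freqs) != len(fv_j.freqs):
        raise ValueError("frequency vectors differ in length")
    return float(np.mean(np.abs(fv_i.freqs - fv_j.freqs)))


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------


def fst_components(
    counts_i: tuple[int, int, int], counts_j: tuple[int, int, int]
) -> tuple[float, float, float] | None:
    """Weir-Cockerham (1984) variance components (a, b, c) for one SNP.

    ``counts_*`` are (hom-ref, het, hom-alt) genotype counts.  Returns
    None when the SNP is monomorphic across both populations (theta
    undefined) and raises if either population has <2 genotyped
    individuals.
    """
    n = np.array([sum(counts_i), sum(counts_j)], dtype=float)
    if np.any(n < 2):
        raise ValueError("each population needs >=2 non-missing individuals")
    p = np.array(
        [
            (2 * counts_i[2] + counts_i[1]) / (2 * n[0]),
            (2 * counts_j[2] + counts_j[1]) / (2 * n[1]),
        ]
    )
    h = np.array([counts_i[1] / n[0], counts_j[1] / n[1]])
    if np.all(p == 0) or np.all(p == 1):
        return None
    r = 2.0
    n_bar = n.mean()
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n * h).sum() / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return float(a), float(b), float(c)


def fst_weir_cockerham_snp(
    counts_i: tuple[int, int, int], counts_j: tuple[int, int, int]
) -> float:
    """Single-SNP theta = a / (a + b + c); NaN when undefined."""
    comps = fst_components(counts_i, counts_j)
    if comps is None:
        return float("nan")
    a, b, c = comps
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return a / denom


def gene_fst(per_snp_components: list[tuple[float, float, float] | None]) -> float:
    """Multi-locus ratio-of-sums theta over a gene's SNPs.

    SNPs with undefined components (monomorphic in both populations)
    are excluded; if none remain the result is NaN.
    """
    defined = [c for c in per_snp_components if c is not None]
    if not defined:
        return float("nan")
    arr = np.asarray(defined, dtype=float)
    denom = arr.sum()
    if denom == 0:
        return float("nan")
    return float(arr[:, 0].sum() / denom)


def gene_fst_from_table(
    vt: VariantTable,
    panel: PopulationPanel,
    gene: GeneRegion,
    pop_i: str,
    pop_j: str,
    combine: str = "ratio_of_sums",
) -> float:
    """Gene-region theta between two populations.

    ``combine`` selects the multi-locus estimator: ``ratio_of_sums``
    (default) or ``average`` of per-SNP ratios.
    """
    rows = panel.sample_indices(vt)
    comps: list[tuple[float, float, float] | None] = []
    for snp in gene.snp_indices:
        ci = genotype_counts(vt.genotypes[rows[pop_i], snp])
        cj = genotype_counts(vt.genotypes[rows[pop_j], snp])
        comps.append(fst_components(ci, cj))
    if combine == "ratio_of_sums":
        return gene_fst(comps)
    if combine == "average":
        thetas = [
            a / (a + b + c)
            for comp in comps
            if comp is not None
            for a, b, c in [comp]
            if (a + b + c) != 0
        ]
        return float(np.mean(thetas)) if thetas else float("nan")
    raise ValueError(f"unknown combine mode {combine!r}")
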